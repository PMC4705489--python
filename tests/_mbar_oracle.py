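"""Independent binless multistate reweighting (MBAR) solver.

Used only as a cross-check oracle for the package's binned WHAM
offsets.  Implemented directly from the self-consistent MBAR equations
with log-sum-exp stabilization; it shares no code with the package.
"""

import numpy as np
from scipy.special import logsumexp


def mbar_offsets(samples_per_window, bias_fns, beta, tol=1e-10, max_iter=50_000):
    """Per-window free energies f_i (f_0 = 0) from biased samples.

    Parameters
    ----------
    samples_per_window : list of 1D arrays
        Coordinate samples from each biased simulation.
    bias_fns : list of callables
        bias_fns[i](x) is the bias energy of window i (same units as 1/beta).
    beta : float
        Inverse temperature.
    """
    x = np.concatenate(samples_per_window)
    n = np.array([len(s) for s in samples_per_window], dtype=float)
    k = len(bias_fns)
    u = np.stack([beta * np.asarray(b(x), dtype=float) for b in bias_fns])  # (k, N)
    f = np.zeros(k)  # dimensionless free energies
    for _ in range(max_iter):
        # log denominator per sample: log sum_j n_j exp(f_j - u_j(x))
        log_den = logsumexp(f[:, None] - u, b=n[:, None], axis=0)
        new_f = -logsumexp(-u - log_den[None, :], axis=1)
        new_f -= new_f[0]
        if np.max(np.abs(new_f - f)) < tol:
            f = new_f
            break
        f = new_f
    return f / beta
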