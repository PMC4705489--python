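attraction_depth: 3.6464280685304065
attraction_flat_until: 6.5
attraction_range: 20.0
attraction_width: 2.0387506073192423
basins:
- center_theta: 150.0
  center_xi: 4.5
  depth: -2.5036171925846715
  label: I
  width_theta: 29.94351893582131
  width_xi: 0.4670383662978809
- center_theta: 150.0
  center_xi: 6.5
  depth: -2.4905159419066805
  label: II
  width_theta: 29.94351893582131
  width_xi: 0.4670383662978809
- center_theta: 30.0
  center_xi: 4.5
  depth: -2.544157518346786
  label: III
  width_theta: 29.94351893582131
  width_xi: 0.4670383662978809
- center_theta: 30.0
  center_xi: 6.5
  depth: -2.3113012961102632
  label: IV
  width_theta: 29.94351893582131
  width_xi: 0.4670383662978809
plateau_level: 0.0
switch_start: 16.0
wall_amplitude: 6.0
wall_decay: 0.28
wall_xi: 3.6
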