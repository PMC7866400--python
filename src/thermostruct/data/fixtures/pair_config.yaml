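proteins:
- active_site:
  - A:19
  - A:21
  chain: A
  class: thermophilic
  id: stable
  pdb: stable.pdb
  t_m: 95.0
  t_opt: 80.0
- active_site:
  - A:27
  - A:29
  chain: A
  class: psychrophilic
  id: floppy
  pdb: floppy.pdb
  t_m: 52.0
  t_opt: 28.0
trajectory:
  dt_ps: 10.0
  n_frames: 200
  seed: 2021
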