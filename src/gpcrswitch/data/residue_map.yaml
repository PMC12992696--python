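ligand:
  residue_name: LIG
  chain_id: A
  atom_roles:
    H1: indole_h
    NT: amine_n
    O1: methoxy_para
    O2: methoxy_meta
    N1: core
    C2: core
    C3: core
    C3A: core
    C4: core
    C5: core
    C6: core
    C7: core
    C7A: core
residues:
- number: 401
  chain: A
  bw: '1.61'
  role: tm
- number: 402
  chain: A
  bw: '1.62'
  role: tm
- number: 403
  chain: A
  bw: '1.63'
  role: tm
- number: 404
  chain: A
  bw: '1.64'
  role: tm
- number: 405
  chain: A
  bw: '2.61'
  role: tm
- number: 406
  chain: A
  bw: '2.62'
  role: tm
- number: 407
  chain: A
  bw: '2.63'
  role: tm
- number: 408
  chain: A
  bw: '2.64'
  role: tm
- number: 409
  chain: A
  bw: '3.61'
  role: tm
- number: 410
  chain: A
  bw: '3.62'
  role: tm
- number: 411
  chain: A
  bw: '3.63'
  role: tm
- number: 412
  chain: A
  bw: '3.64'
  role: tm
- number: 413
  chain: A
  bw: '4.61'
  role: tm
- number: 414
  chain: A
  bw: '4.62'
  role: tm
- number: 415
  chain: A
  bw: '4.63'
  role: tm
- number: 416
  chain: A
  bw: '4.64'
  role: tm
- number: 417
  chain: A
  bw: '5.61'
  role: tm
- number: 418
  chain: A
  bw: '5.62'
  role: tm
- number: 419
  chain: A
  bw: '5.63'
  role: tm
- number: 420
  chain: A
  bw: '5.64'
  role: tm
- number: 421
  chain: A
  bw: '6.61'
  role: tm
- number: 422
  chain: A
  bw: '6.62'
  role: tm
- number: 423
  chain: A
  bw: '6.63'
  role: tm
- number: 424
  chain: A
  bw: '6.64'
  role: tm
- number: 425
  chain: A
  bw: '7.61'
  role: tm
- number: 426
  chain: A
  bw: '7.62'
  role: tm
- number: 427
  chain: A
  bw: '7.63'
  role: tm
- number: 428
  chain: A
  bw: '7.64'
  role: tm
- number: 501
  chain: A
  bw: '23.50'
  role: vestibule
- number: 502
  chain: A
  bw: '23.51'
  role: vestibule
- number: 503
  chain: A
  bw: '23.52'
  role: vestibule
- number: 120
  chain: A
  bw: '2.50'
  role: na_site
- number: 155
  chain: A
  bw: '3.32'
  role: anchor
- number: 160
  chain: A
  bw: '3.37'
  role: base
- number: 162
  chain: A
  bw: '3.39'
  role: na_backup
- number: 173
  chain: A
  bw: '3.50'
  role: ionic_lock_arg
- number: 231
  chain: A
  bw: '5.35'
  role: depth_anchor
- number: 239
  chain: A
  bw: '5.44'
  role: polar_ser1
- number: 242
  chain: A
  bw: '5.46'
  role: polar_ser2
- number: 318
  chain: A
  bw: '6.30'
  role: ionic_lock_glu
- number: 322
  chain: A
  bw: '6.34'
  role: tm6_gap
- number: 332
  chain: A
  bw: '6.44'
  role: na_lid
- number: 336
  chain: A
  bw: '6.48'
  role: toggle
- number: 343
  chain: A
  bw: '6.55'
  role: polar_asn
- number: 380
  chain: A
  bw: '7.49'
  role: na_stabilizer
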