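n_ambient: 1.0
chromophores:
  wavelengths:
  - 450.0
  - 550.0
  - 650.0
  - 750.0
  - 850.0
  - 950.0
  - 1050.0
  mua_water:
  - 9.2e-06
  - 4.5e-05
  - 0.00032
  - 0.0028
  - 0.0043
  - 0.03
  - 0.016
  mua_Hb:
  - 55.3
  - 28.6
  - 2.01
  - 0.753
  - 0.37
  - 0.371
  - 0.482
  mua_HbO2:
  - 33.7
  - 23.0
  - 0.197
  - 0.301
  - 0.567
  - 0.645
  - 0.616
  mua_other:
  - 0.0025
  - 0.0025
  - 0.0025
  - 0.0025
  - 0.0025
  - 0.0025
  - 0.0025
  melanin_scale: 66000000000.0
  melanin_exponent: -3.33
layers:
- name: stratum_corneum
  thickness: 0.02
  mus:
  - 60.61
  - 41.74
  - 22.33
  - 15.05
  - 13.32
  - 9.5
  - 7.52
  g: 0.9
  n: 1.37
  v_blood: 0.0
  v_water: 0.05
  v_mel: 0.0
  oxygen_saturation: 0.75
  epidermis_middle_term: water
- name: epidermis
  thickness: 0.25
  mus:
  - 60.61
  - 41.74
  - 22.33
  - 15.05
  - 13.32
  - 9.5
  - 7.52
  g: 0.9
  n: 1.37
  v_blood: 0.0
  v_water: 0.2
  v_mel: 0.2
  oxygen_saturation: 0.75
  epidermis_middle_term: water
- name: papillary_dermis
  thickness: 0.1
  mus:
  - 60.61
  - 41.74
  - 22.33
  - 15.05
  - 13.32
  - 9.5
  - 7.52
  g: 0.9
  n: 1.37
  v_blood: 0.04
  v_water: 0.5
  v_mel: 0.0
  oxygen_saturation: 0.75
  epidermis_middle_term: water
- name: upper_blood_net_dermis
  thickness: 0.08
  mus:
  - 60.61
  - 41.74
  - 22.33
  - 15.05
  - 13.32
  - 9.5
  - 7.52
  g: 0.9
  n: 1.37
  v_blood: 0.3
  v_water: 0.6
  v_mel: 0.0
  oxygen_saturation: 0.75
  epidermis_middle_term: water
- name: reticular_dermis
  thickness: 0.2
  mus:
  - 60.61
  - 41.74
  - 22.33
  - 15.05
  - 13.32
  - 9.5
  - 7.52
  g: 0.9
  n: 1.37
  v_blood: 0.04
  v_water: 0.7
  v_mel: 0.0
  oxygen_saturation: 0.75
  epidermis_middle_term: water
- name: deep_blood_net_dermis
  thickness: 0.3
  mus:
  - 60.61
  - 41.74
  - 22.33
  - 15.05
  - 13.32
  - 9.5
  - 7.52
  g: 0.9
  n: 1.37
  v_blood: 0.1
  v_water: 0.7
  v_mel: 0.0
  oxygen_saturation: 0.75
  epidermis_middle_term: water
- name: subcutaneous_tissue
  thickness: 2.0
  mus:
  - 60.61
  - 41.74
  - 22.33
  - 15.05
  - 13.32
  - 9.5
  - 7.52
  g: 0.9
  n: 1.37
  v_blood: 0.05
  v_water: 0.7
  v_mel: 0.0
  oxygen_saturation: 0.75
  epidermis_middle_term: water
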