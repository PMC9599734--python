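# Chemical component codes accepted by the site finder, per role.
# The PDB chemical dictionary evolves; edit or extend this file and pass it
# via PipelineConfig.from_yaml / the --components CLI option.
components:
  ntp:            # native triphosphates
    - ATP
    - GTP
  ndp:            # diphosphates (need a gamma-phosphate mimic to count)
    - ADP
    - GDP
  non_hydrolyzable:
    - ANP         # AMP-PNP
    - GNP         # GMP-PNP
    - ACP         # AMP-PCP
    - GCP         # GMP-PCP
    - AGS         # ATP-gamma-S
    - GSP         # GTP-gamma-S
  mimic:          # gamma-phosphate mimicking moieties
    - ALF         # AlF4-
    - AF3         # AlF3
    - MGF         # MgF3-
    - BEF         # BeF3
    - VO4         # vanadate
  phosphate:      # inorganic phosphate (post-hydrolysis sites)
    - PO4
    - PI
    - 2HP
  ion:
    - MG
    - MN
    - CA
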