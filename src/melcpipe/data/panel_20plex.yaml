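# Packaged 20-plex MELC panel for neuroblastoma bone-marrow samples:
# staining/imaging sequence with negative-control (bare secondary antibody)
# acquisitions preceding the three indirectly stained markers.
# Mutually exclusive partners for background normalization are a study-design
# choice and are left to the user's configuration.
panel:
  image_size_px: 2018
  pixel_size_um: 0.45
  nuclear_marker: PI
  steps:
    - {index: 1, marker: FAIM2, conjugate: FITC, nc_partner: NC-SwaRb-FITC}
    - {index: 2, marker: CD25, conjugate: PE}
    - {index: 3, marker: PD-1, conjugate: Cy3, nc_partner: NC-MsaBiot-Cy3}
    - {index: 4, marker: CD29, conjugate: FITC}
    - {index: 5, marker: CD24, conjugate: FITC}
    - {index: 6, marker: GD2, conjugate: FITC}
    - {index: 7, marker: CD3, conjugate: PE}
    - {index: 8, marker: CD34, conjugate: PE}
    - {index: 9, marker: CD4, conjugate: PE}
    - {index: 10, marker: CD20, conjugate: PE}
    - {index: 11, marker: CD8, conjugate: PE}
    - {index: 12, marker: CD14, conjugate: PE}
    - {index: 13, marker: CD44, conjugate: PE}
    - {index: 14, marker: CD45, conjugate: PE}
    - {index: 15, marker: CD56, conjugate: PE}
    - {index: 16, marker: HLA-DR, conjugate: PE}
    - {index: 17, marker: HLA-ABC, conjugate: PE}
    - {index: 18, marker: B7-H3, conjugate: PE}
    - {index: 19, marker: VIM, conjugate: FITC, nc_partner: NC-GtaCh-FITC}
    - {index: 20, marker: PI, conjugate: PI}
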