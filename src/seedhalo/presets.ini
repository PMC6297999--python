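# Per-species segmentation presets.
#
# Bands are inclusive [low, high] on the 8-bit HSV planes; area filters are
# in mm^2.  Only the Linum (flax) thresholds were calibrated on stained
# plates; the other species ship the same bands as a starting point and
# SHOULD be recalibrated on a representative plate (see docs/methods.md,
# "Recalibrating presets") -- seed and halo sizes differ strongly between
# species, which is reflected in the area filters below.

[linum]
mucilage_h = 172,255
mucilage_s = 24,255
mucilage_v = 85,255
seed_h = 0,255
seed_s = 0,255
seed_v = 0,70
mucilage_area_mm2 = 18,315
seed_area_mm2 = 0.5,50

[arabidopsis]
mucilage_h = 172,255
mucilage_s = 24,255
mucilage_v = 85,255
seed_h = 0,255
seed_s = 0,255
seed_v = 0,70
mucilage_area_mm2 = 0.5,20
seed_area_mm2 = 0.02,1

[camelina]
mucilage_h = 172,255
mucilage_s = 24,255
mucilage_v = 85,255
seed_h = 0,255
seed_s = 0,255
seed_v = 0,70
mucilage_area_mm2 = 4,80
seed_area_mm2 = 0.2,10

[plantago]
mucilage_h = 172,255
mucilage_s = 24,255
mucilage_v = 85,255
seed_h = 0,255
seed_s = 0,255
seed_v = 0,70
mucilage_area_mm2 = 4,80
seed_area_mm2 = 0.2,10

[capsella]
mucilage_h = 172,255
mucilage_s = 24,255
mucilage_v = 85,255
seed_h = 0,255
seed_s = 0,255
seed_v = 0,70
mucilage_area_mm2 = 2,50
seed_area_mm2 = 0.1,5
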