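# Demonstration knowledge base — SYNTHETIC values for format illustration
# and examples only.  The trapezoid corners, similarity matrix and colour
# matrices here are NOT authoritative expert knowledge for any real fauna.
#
# Colour order everywhere: yellow, orange, red, green, blue, brown, black.
# Trapezoids are [a, b, c, d]: zero outside (a, d), one on [b, c].
# "permissibility" encodes the exclusion matrix E: 1 = no penalty (default),
# 0 = observing that colour excludes the class.
schema_version: 1
colour_similarity:
  - [1.0, 0.4, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.4, 1.0, 0.5, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.5, 1.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 1.0, 0.3, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.3, 1.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.2]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.2, 1.0]
biotopes: [lake, puddle, canal, garden_pool, quarry, wetland, brook,
           headwaters_and_spring, organic_soil_wetland, pond, river,
           oxbow_lake, reservoir_in_valley, terrestrial_habitat]
species:
  - id: demo_hawker
    suborder: anisoptera
    seasonality: [150, 170, 240, 270]
    altitude: [100, 200, 700, 1100]
    colours:
      male:
        additive: {blue: 1.0, green: 0.6}
        permissibility: {red: 0.0}
      female:
        additive: {brown: 1.0, yellow: 0.5}
        permissibility: {}
  - id: demo_darter
    suborder: anisoptera
    seasonality: [170, 190, 270, 300]
    altitude: [100, 150, 500, 800]
    colours:
      male:
        additive: {red: 1.0, orange: 0.7}
        permissibility: {blue: 0.0}
      female:
        additive: {yellow: 1.0, brown: 0.8}
        permissibility: {}
  - id: demo_bluet
    suborder: zygoptera
    seasonality: [120, 140, 220, 250]
    altitude: [100, 150, 600, 900]
    colours:
      male:
        additive: {blue: 1.0, black: 0.8}
        permissibility: {red: 0.0, brown: 0.0}
      female:
        additive: {green: 1.0, brown: 0.6}
        permissibility: {}
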