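"""V2000 blocks for the built-in toy molecules.

Small, reviewable structures with explicit 2D coordinates; the two
butan-2-ol blocks carry the wedge bonds that distinguish the
enantiomers.
"""

MOLBLOCKS = {
    "methane": """
     RDKit          2D

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
""",
    "ethanol": """
     RDKit          2D

  3  2  0  0  0  0  0  0  0  0999 V2000
   -1.2990   -0.2500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990   -0.2500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
""",
    "ethene": """
     RDKit          2D

  2  1  0  0  0  0  0  0  0  0999 V2000
   -0.7500    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
M  END
""",
    "water": """
     RDKit          2D

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
M  END
""",
    "benzene": """
     RDKit          2D

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
""",
    "butadiene": """
     RDKit          2D

  4  3  0  0  0  0  0  0  0  0999 V2000
   -1.9796   -0.1365    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5994    0.4508    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5994   -0.4508    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9796    0.1365    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
M  END
""",
    "cyclohexene": """
     RDKit          2D

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  1  1  0
M  END
""",
    "acetic_acid": """
     RDKit          2D

  4  3  0  0  0  0  0  0  0  0999 V2000
   -1.2990   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.5000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990   -0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  2  4  1  0
M  END
""",
    "ethyl_acetate": """
     RDKit          2D

  6  5  0  0  0  0  0  0  0  0999 V2000
   -2.8748   -0.2197    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4825    0.3386    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3029   -0.5880    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.0893   -0.0297    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2689   -0.9563    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3020    1.4551    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  4  6  2  0
M  END
""",
    "butanone": """
     RDKit          2D

  5  4  0  0  0  0  0  0  0  0999 V2000
   -2.0785    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7794    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.8187    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -1.5000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  3  5  2  0
M  END
""",
    "r_butan_2_ol": """
     RDKit          2D

  5  4  0  0  0  0  0  0  0  0999 V2000
   -2.0785    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7794    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.8187    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -1.5000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  1
  3  5  1  0
M  END
""",
    "s_butan_2_ol": """
     RDKit          2D

  5  4  0  0  0  0  0  0  0  0999 V2000
   -2.0785    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7794    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.8187    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -1.5000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  6
  3  5  1  0
M  END
""",
    "sulfuric_acid": """
     RDKit          2D

  5  4  0  0  0  0  0  0  0  0999 V2000
   -1.2990   -0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -0.0000    0.0000 S   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  2  4  2  0
  2  5  1  0
M  END
""",
    "hexadiene": """
     RDKit          2D

  6  5  0  0  0  0  0  0  0  0999 V2000
   -3.2624   -0.2097    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9270    0.4734    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6677   -0.3416    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6677    0.3416    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9270   -0.4734    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.2624    0.2097    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  3
  4  5  1  0
  5  6  1  0
M  END
""",
    "naphthalene": """
     RDKit          2D

 10 11  0  0  0  0  0  0  0  0999 V2000
   -2.5981   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5981    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2990    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0000    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990   -1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2990   -1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  8  9  1  0
  9 10  2  0
 10  1  1  0
  9  4  1  0
M  END
""",
    "methanol": """
     RDKit          2D

  2  1  0  0  0  0  0  0  0  0999 V2000
   -0.7500    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
""",
    "toluene": """
     RDKit          2D

  7  7  0  0  0  0  0  0  0  0999 V2000
    2.5714    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0714   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3214   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1786   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9286    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1786    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3214    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  7  2  1  0
M  END
""",
    "r_butan_2_amine": """
     RDKit          2D

  5  4  0  0  0  0  0  0  0  0999 V2000
   -2.0785    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7794    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.8187    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -1.5000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  1
  3  5  1  0
M  END
""",
    "s_butan_2_amine": """
     RDKit          2D

  5  4  0  0  0  0  0  0  0  0999 V2000
   -2.0785    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7794    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.8187    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5196   -1.5000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  6
  3  5  1  0
M  END
""",
}
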