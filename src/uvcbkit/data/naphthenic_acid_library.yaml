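name: naphthenic-acid-library
description: 'Virtual library design for the organic (naphthenic acid) components
  of metal naphthenates: eight saturated core ring systems spanning hydrogen deficiencies
  Z=-2..-6, 26 C1-C6 alkyl substituents, and 15 C2-C5 carboxylic-acid substituents.
  Attachment positions index atoms of the structure SMILES as written. Enumerating
  one alkyl plus one acid over all declared positions and deduplicating on InChIKey
  connectivity blocks yields 11850 unique structures.'
rules:
  one_alkyl_one_acid: true
  allow_geminal: false
scaffolds:
- id: S1
  label: cyclopentane
  ring_class: Z-2
  structure: C1CCCC1
  alkyl_positions:
  - 0
  - 1
  - 2
  - 3
  - 4
  acid_positions:
  - 0
  - 1
  - 2
  - 3
  - 4
- id: S2
  label: cyclohexane
  ring_class: Z-2
  structure: C1CCCCC1
  alkyl_positions:
  - 0
  - 1
  - 2
  - 3
  - 4
  - 5
  acid_positions:
  - 0
  - 1
  - 2
  - 3
  - 4
  - 5
- id: S3
  label: cyclohexane with methylene attachment arm
  ring_class: Z-2
  structure: CC1CCCCC1
  alkyl_positions:
  - 0
  acid_positions:
  - 4
- id: S4
  label: bicyclo[3.3.0]octane
  ring_class: Z-4
  structure: C1CCC2CCCC12
  alkyl_positions:
  - 0
  - 1
  - 4
  acid_positions:
  - 0
  - 1
  - 4
- id: S5
  label: bicyclo[4.3.0]nonane (hydrindane)
  ring_class: Z-4
  structure: C1CCC2CCCCC12
  alkyl_positions:
  - 0
  - 2
  - 4
  acid_positions:
  - 0
  - 2
  - 4
- id: S6
  label: bicyclo[4.4.0]decane (decalin)
  ring_class: Z-4
  structure: C1CCC2CCCCC2C1
  alkyl_positions:
  - 0
  - 1
  - 4
  acid_positions:
  - 0
  - 1
  - 4
- id: S7
  label: bicyclohexyl
  ring_class: Z-4
  structure: C1CCCCC1C1CCCCC1
  alkyl_positions:
  - 0
  - 1
  - 4
  acid_positions:
  - 0
  - 1
  - 4
- id: S8
  label: perhydrofluorene
  ring_class: Z-6
  structure: C1CCC2C(C1)CC1CCCCC12
  alkyl_positions:
  - 0
  - 2
  - 9
  acid_positions:
  - 0
  - 2
  - 9
alkyl_groups:
- id: R01
  label: methyl
  structure: '*C'
- id: R02
  label: ethyl
  structure: '*CC'
- id: R03
  label: propan-2-yl
  structure: '*C(C)C'
- id: R04
  label: propyl
  structure: '*CCC'
- id: R05
  label: tert-butyl
  structure: '*C(C)(C)C'
- id: R06
  label: butan-2-yl
  structure: '*C(C)CC'
- id: R07
  label: 2-methylpropyl
  structure: '*CC(C)C'
- id: R08
  label: butyl
  structure: '*CCCC'
- id: R09
  label: 2-methylbutan-2-yl
  structure: '*C(C)(C)CC'
- id: R10
  label: 3-methylbutan-2-yl
  structure: '*C(C)C(C)C'
- id: R11
  label: pentan-2-yl
  structure: '*C(C)CCC'
- id: R12
  label: pentan-3-yl
  structure: '*C(CC)CC'
- id: R13
  label: 2,2-dimethylpropyl
  structure: '*CC(C)(C)C'
- id: R14
  label: 2-methylbutyl
  structure: '*CC(C)CC'
- id: R15
  label: 3-methylbutyl
  structure: '*CCC(C)C'
- id: R16
  label: pentyl
  structure: '*CCCCC'
- id: R17
  label: 2,2-dimethylbutyl
  structure: '*CC(C)(C)CC'
- id: R18
  label: 2,3-dimethylbutyl
  structure: '*CC(C)C(C)C'
- id: R19
  label: 2-methylpentyl
  structure: '*CC(C)CCC'
- id: R20
  label: 2-ethylbutyl
  structure: '*CC(CC)CC'
- id: R21
  label: 3,3-dimethylbutyl
  structure: '*CCC(C)(C)C'
- id: R22
  label: 3-methylpentyl
  structure: '*CCC(C)CC'
- id: R23
  label: 4-methylpentyl
  structure: '*CCCC(C)C'
- id: R24
  label: hexyl
  structure: '*CCCCCC'
- id: R25
  label: hexan-2-yl
  structure: '*C(C)CCCC'
- id: R26
  label: hexan-3-yl
  structure: '*C(CC)CCC'
acid_groups:
- id: Q01
  label: carboxymethyl
  structure: '*CC(=O)O'
- id: Q02
  label: 1-carboxyethyl
  structure: '*C(C)C(=O)O'
- id: Q03
  label: 2-carboxyethyl
  structure: '*CCC(=O)O'
- id: Q04
  label: 1-carboxy-1-methylethyl
  structure: '*C(C)(C)C(=O)O'
- id: Q05
  label: 2-carboxy-1-methylethyl
  structure: '*C(C)CC(=O)O'
- id: Q06
  label: 1-carboxypropyl
  structure: '*C(CC)C(=O)O'
- id: Q07
  label: 2-carboxypropyl
  structure: '*CC(C)C(=O)O'
- id: Q08
  label: 3-carboxypropyl
  structure: '*CCCC(=O)O'
- id: Q09
  label: 4-carboxybutyl
  structure: '*CCCCC(=O)O'
- id: Q10
  label: 3-carboxy-1-methylpropyl
  structure: '*C(C)CCC(=O)O'
- id: Q11
  label: 3-carboxy-2-methylpropyl
  structure: '*CC(C)CC(=O)O'
- id: Q12
  label: 3-carboxybutyl
  structure: '*CCC(C)C(=O)O'
- id: Q13
  label: 2-carboxy-1-ethylethyl
  structure: '*C(CC)CC(=O)O'
- id: Q14
  label: 2-carboxy-1-methylpropyl
  structure: '*C(C)C(C)C(=O)O'
- id: Q15
  label: 2-carboxy-2-methylpropyl
  structure: '*CC(C)(C)C(=O)O'
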