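# Default tracked-atom selections, CHARMM36 atom naming.
#
# Protein probes (construct numbering of the PKC-delta C1b domain):
#   L250  backbone amide nitrogen
#   W252  indole nitrogen
#   S240  side-chain oxygen or backbone amide nitrogen (minimum over the set)
#   P241  backbone carbonyl oxygen or amide nitrogen
#   K256/K260/K271/K275  side-chain amine nitrogen
# Lipid probes:
#   cholesterol hydroxyl oxygen; phosphatidylserine phosphate oxygens and
#   carboxylic oxygens; PE/PC/PIP phosphate oxygens; PA phosphate oxygen;
#   ceramide glycerol hydroxyl oxygens.
#
# Atom tokens below follow CHARMM36 residue topologies; they are defaults,
# not chemistry the code depends on — override any token to match your
# topology's naming (e.g. a different PS carboxylate oxygen convention).
groups:
  L250:
    role: protein_probe
    atoms: [[250, N]]
  W252:
    role: protein_probe
    atoms: [[252, NE1]]
  S240:
    role: protein_probe
    atoms: [[240, OG], [240, N]]
  P241:
    role: protein_probe
    atoms: [[241, O], [241, N]]
  K256:
    role: protein_probe
    atoms: [[256, NZ]]
  K260:
    role: protein_probe
    atoms: [[260, NZ]]
  K271:
    role: protein_probe
    atoms: [[271, NZ]]
  K275:
    role: protein_probe
    atoms: [[275, NZ]]
  CHOL:
    role: lipid_probe
    lipid_class: CHOL
    atoms: [[CHL1, O3]]
  PS:
    role: lipid_probe
    lipid_class: PS
    # phosphate oxygens + serine carboxylate oxygens
    atoms: [[SOPS, O11], [SOPS, O12], [SOPS, O13], [SOPS, O14], [SOPS, O13A], [SOPS, O13B]]
  PE:
    role: lipid_probe
    lipid_class: PE
    atoms: [[POPE, O11], [POPE, O12], [POPE, O13], [POPE, O14]]
  PC:
    role: lipid_probe
    lipid_class: PC
    atoms: [[POPC, O11], [POPC, O12], [POPC, O13], [POPC, O14]]
  PIP:
    role: lipid_probe
    lipid_class: PIP
    atoms: [[PLPIP35, O11], [PLPIP35, O12], [PLPIP35, O13], [PLPIP35, O14]]
  PA:
    role: lipid_probe
    lipid_class: PA
    atoms: [[POPA, O11], [POPA, O12], [POPA, O13], [POPA, O14]]
  CER:
    role: lipid_probe
    lipid_class: CER
    atoms: [[CER160, O1], [CER160, O3]]
  G253_CA:
    role: reference
    atoms: [[253, CA]]
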