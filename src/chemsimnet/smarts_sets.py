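"""Builtin SMARTS pattern set for the pattern-defined fingerprint engine.

A compact functional-group / substructure vocabulary usable when no external
pattern file is supplied. The engine itself (`features.smarts_pattern_fingerprint`)
accepts any list of SMARTS, so larger published vocabularies (substructure-key
or Klekota-Roth style sets) can be plugged in from a pattern file.
"""

BUILTIN_SMARTS: tuple[str, ...] = (
    "[CX4]",              # sp3 carbon
    "[CX3]=[CX3]",        # alkene
    "[CX2]#C",            # alkyne
    "c",                  # aromatic carbon
    "c1ccccc1",           # benzene ring
    "[cR2]",              # fused aromatic atom
    "[OX2H]",             # hydroxyl
    "[OX2H][CX4]",        # aliphatic alcohol
    "[OX2H]c",            # phenol
    "[CX3]=[OX1]",        # carbonyl
    "[CX3](=O)[OX2H1]",   # carboxylic acid
    "[CX3](=O)[OX2][#6]", # ester
    "[CX3H1](=O)",        # aldehyde
    "[CX3](=O)[#6]",      # ketone
    "[OX2]([#6])[#6]",    # ether
    "[NX3;H2]",           # primary amine
    "[NX3;H1]([#6])[#6]", # secondary amine
    "[NX3]([#6])([#6])[#6]",  # tertiary amine
    "[NX3][CX3](=[OX1])", # amide N
    "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",  # nitro
    "[NX2]=[OX1]",        # nitroso
    "[NX1]#[CX2]",        # nitrile
    "n",                  # aromatic nitrogen
    "[#16]",              # any sulfur
    "[SX2H]",             # thiol
    "[#16X2]([#6])[#6]",  # thioether
    "[#16X4](=[OX1])(=[OX1])",  # sulfonyl
    "[CX3]=[SX1]",        # thiocarbonyl
    "[F]",                # fluorine
    "[Cl]",               # chlorine
    "[Br]",               # bromine
    "[I]",                # iodine
    "[#6][F,Cl,Br,I]",    # carbon-halogen bond
    "[CX4]([F,Cl,Br,I])([F,Cl,Br,I])",  # gem-dihalide carbon
    "[#15]",              # phosphorus
    "[PX4](=[OX1])",      # phosphoryl
    "[#5]",               # boron
    "[Si]",               # silicon
    "[#8-,#8H0X1]",       # oxide / charged oxygen
    "[!#1;!#6;!#7;!#8;!#9;!#16;!#17;!#35;!#53;!#15;!#5;!#14]",  # other heteroatom (metals etc.)
    "[+,++,+++]",         # cation
    "[-,--,---]",         # anion
    "[R]",                # any ring atom
    "[r3,r4]",            # small (strained) ring
    "[r5]",               # five-membered ring
    "[r6]",               # six-membered ring
    "[CX4H3]",            # methyl
    "[CX4H2]",            # methylene
    "[OX2r3]",            # epoxide oxygen
    "[NX3r]",             # ring nitrogen (non-aromatic)
)
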