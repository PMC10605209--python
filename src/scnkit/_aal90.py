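"""AAL90 atlas region abbreviations.

The 90 cortical/subcortical regions of the Automated Anatomical Labeling
atlas, in the conventional numbering (odd indices left hemisphere, even
indices right), used as default node labels for structural covariance
networks.
"""

_BASE = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
]

#: AAL90 region labels, interleaved left/right: PreCG.L, PreCG.R, SFGdor.L, ...
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{name}.{hemi}" for name in _BASE for hemi in ("L", "R")
)

assert len(AAL90_LABELS) == 90
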