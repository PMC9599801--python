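"""International extended 10-20 montage labels used throughout the package.

The analysis montage has 62 scalp channels (a 64-electrode cap minus the
two electrooculogram channels HEO/VEO).  The mastoid electrodes M1/M2 serve
as the reference pair and the EOG channels exist only on raw recordings;
neither enters the connectivity analysis.
"""

from __future__ import annotations

# 62 scalp channels, frontal to occipital, left to right.
SCALP_62: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
    "CB1", "CB2",
)

MASTOIDS: tuple[str, str] = ("M1", "M2")
MASTOID_SYNONYMS: dict[str, str] = {"A1": "M1", "A2": "M2"}
EOG_LABELS: tuple[str, ...] = ("HEO", "VEO")

# The eight electrode pairs singled out for the alpha-band group comparison:
# three inter-hemispheric and five intra-hemispheric pairs.
NAMED_PAIRS: tuple[tuple[str, str], ...] = (
    ("F4", "P3"), ("P4", "CP3"), ("CP5", "O2"),          # inter-hemispheric
    ("C3", "P3"), ("C4", "P8"), ("F3", "C5"),            # intra-hemispheric
    ("F8", "P8"), ("CP3", "O1"),
)


def is_posterior_central(label: str) -> bool:
    """True for parietal / parieto-occipital / central channels (P, PO, C, CP).

    These sites carry the strongest resting alpha coupling in the synthetic
    cohort, mirroring the posterior concentration seen in group-mean
    connectivity matrices of eyes-closed EEG.
    """
    for prefix in ("PO", "CP", "P", "C"):
        if label.startswith(prefix) and not label.startswith("CB"):
            return True
    return False


# 16-channel reduced montage: covers all channels of the eight named pairs
# plus the three midline sites, in cap order.
REDUCED_16: tuple[str, ...] = (
    "F3", "Fz", "F4", "F8",
    "C5", "C3", "C4",
    "CP5", "CP3",
    "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)


def default_labels(n_channels: int) -> list[str]:
    """Default labels for an ``n_channels`` montage.

    62 channels: the full cap.  16: the curated reduced montage (covers the
    named electrode pairs).  Anything else samples evenly across the cap —
    a spread of scalp sites, useful for small test montages.
    """
    if n_channels > len(SCALP_62):
        raise ValueError(
            f"montage has {len(SCALP_62)} labels, {n_channels} requested"
        )
    if n_channels == len(SCALP_62):
        return list(SCALP_62)
    if n_channels == len(REDUCED_16):
        return list(REDUCED_16)
    import numpy as np

    idx = np.linspace(0, len(SCALP_62) - 1, n_channels).round().astype(int)
    return [SCALP_62[i] for i in idx]
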