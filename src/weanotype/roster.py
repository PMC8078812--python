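"""Fixed taxon roster for the synthetic weaning cohort.

The roster mimics the taxonomic breadth of 16S surveys of the piglet hindgut:
~80 genera in ~40 families across 6 phyla (plus a small unknown-phylum tail
used to exercise the known-phylum filter). Thirteen genera carry the
enterotype-discriminating mean profiles; the remainder are "filler" genera
whose mass is allocated per enterotype so that each enterotype composition
meets a phylum budget, and whose trajectory across the maturational gradient
E1->E4 is controlled by a coarse tilt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

UNKNOWN = "unknown"

#: phylum order used throughout
PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Proteobacteria",
    "Spirochaetes",
    "Fusobacteria",
    "Actinobacteria",
    UNKNOWN,
)

#: mean relative abundance (%) of the 13 discriminating genera in E1..E4
DISCRIMINATING_GENERA: dict[str, tuple[str, str, tuple[float, float, float, float]]] = {
    # genus: (family, phylum, (E1, E2, E3, E4) mean %)
    "Prevotella": ("Prevotellaceae", "Bacteroidetes", (3.87, 1.32, 11.29, 31.4)),
    "Faecalibacterium": ("Ruminococcaceae", "Firmicutes", (0.35, 0.24, 2.41, 11.08)),
    "Roseburia": ("Lachnospiraceae", "Firmicutes", (0.24, 0.17, 1.20, 4.36)),
    "Lachnospira": ("Lachnospiraceae", "Firmicutes", (0.02, 0.05, 0.48, 1.08)),
    "Bacteroides": ("Bacteroidaceae", "Bacteroidetes", (16.10, 5.71, 0.59, 0.63)),
    "Coprococcus": ("Lachnospiraceae", "Firmicutes", (0.12, 0.35, 0.86, 0.93)),
    "Treponema": ("Spirochaetaceae", "Spirochaetes", (0.54, 1.21, 3.77, 1.09)),
    "Paludibacter": ("Porphyromonadaceae", "Bacteroidetes", (0.02, 0.26, 0.27, 0.06)),
    "Ruminococcus": ("Ruminococcaceae", "Firmicutes", (1.27, 2.25, 2.16, 1.34)),
    "Mitsuokella": ("Veillonellaceae", "Firmicutes", (0.02, 0.01, 0.03, 0.21)),
    "Oscillospira": ("Ruminococcaceae", "Firmicutes", (2.43, 3.59, 2.79, 2.05)),
    "Lactobacillus": ("Lactobacillaceae", "Firmicutes", (1.82, 0.88, 0.78, 0.68)),
    "Campylobacter": ("Campylobacteraceae", "Proteobacteria", (1.52, 0.57, 1.14, 1.11)),
}

#: per-enterotype phylum budgets (%, columns E1..E4). Each column sums to 100.
#: Chosen so the pi-mixture pooled shares land near the study-wide phylum
#: means (Firmicutes 63, Bacteroidetes 29, Proteobacteria 5.2, Spirochaetes
#: 1.7, Fusobacteria 1.3) while every budget exceeds the mass already claimed
#: by the discriminating genera of that phylum.
PHYLUM_BUDGETS: dict[str, tuple[float, float, float, float]] = {
    "Firmicutes": (57.6, 69.6, 62.0, 59.6),
    "Bacteroidetes": (31.0, 20.0, 28.0, 34.0),
    "Proteobacteria": (6.5, 5.5, 4.5, 3.6),
    "Spirochaetes": (0.8, 1.5, 4.0, 1.2),
    "Fusobacteria": (2.5, 1.6, 0.6, 0.5),
    "Actinobacteria": (1.2, 1.4, 0.5, 0.7),
    UNKNOWN: (0.4, 0.4, 0.4, 0.4),
}

#: coarse abundance trajectories along the E1->E4 maturational gradient.
#: "down"/"up" are monotone; "e1".."e4" are enterotype specialists that give
#: each state signature filler taxa (observed enterotypes are discriminated
#: by more taxa than the printed shortlist).
TILTS = {
    "down": (2.0, 1.2, 0.6, 0.35),
    "flat": (1.0, 1.0, 1.0, 1.0),
    "up": (0.35, 0.6, 1.2, 2.0),
    "e1": (2.6, 0.7, 0.45, 0.35),
    "e2": (0.7, 2.4, 0.7, 0.45),
    "e3": (0.45, 0.7, 2.4, 0.7),
    "e4": (0.4, 0.5, 0.9, 2.6),
}

#: filler genera: (genus, family, phylum, base weight, tilt).  The base
#: weight fixes the genus share within its (phylum, enterotype) filler budget
#: after tilting; absolute scale is irrelevant.
FILLER_GENERA: list[tuple[str, str, str, float, str]] = [
    # Firmicutes
    ("Blautia", "Lachnospiraceae", "Firmicutes", 2.0, "up"),
    ("Dorea", "Lachnospiraceae", "Firmicutes", 1.0, "e3"),
    ("Anaerostipes", "Lachnospiraceae", "Firmicutes", 0.4, "up"),
    ("Moryella", "Lachnospiraceae", "Firmicutes", 0.3, "flat"),
    ("Butyrivibrio", "Lachnospiraceae", "Firmicutes", 0.3, "e4"),
    (UNKNOWN, "Lachnospiraceae", "Firmicutes", 4.0, "e3"),
    ("Clostridium", "Clostridiaceae", "Firmicutes", 2.8, "down"),
    ("SMB53", "Clostridiaceae", "Firmicutes", 1.2, "e1"),
    ("Sarcina", "Clostridiaceae", "Firmicutes", 0.5, "down"),
    ("Christensenella", "Christensenellaceae", "Firmicutes", 2.8, "e2"),
    ("Gemmiger", "Ruminococcaceae", "Firmicutes", 0.8, "flat"),
    ("Butyricicoccus", "Ruminococcaceae", "Firmicutes", 0.4, "flat"),
    ("Anaerotruncus", "Ruminococcaceae", "Firmicutes", 0.3, "e2"),
    (UNKNOWN, "Ruminococcaceae", "Firmicutes", 5.5, "e2"),
    ("Megasphaera", "Veillonellaceae", "Firmicutes", 1.2, "e4"),
    ("Dialister", "Veillonellaceae", "Firmicutes", 0.8, "up"),
    ("Selenomonas", "Veillonellaceae", "Firmicutes", 0.3, "e4"),
    ("Anaerovibrio", "Veillonellaceae", "Firmicutes", 0.4, "up"),
    ("Acidaminococcus", "Veillonellaceae", "Firmicutes", 0.3, "up"),
    ("Megamonas", "Veillonellaceae", "Firmicutes", 0.3, "e3"),
    ("Veillonella", "Veillonellaceae", "Firmicutes", 0.3, "up"),
    ("Phascolarctobacterium", "Veillonellaceae", "Firmicutes", 0.8, "e3"),
    ("Streptococcus", "Streptococcaceae", "Firmicutes", 1.2, "e1"),
    ("Lactococcus", "Streptococcaceae", "Firmicutes", 0.3, "e1"),
    ("Enterococcus", "Enterococcaceae", "Firmicutes", 0.5, "e1"),
    ("Turicibacter", "Turicibacteraceae", "Firmicutes", 0.6, "e2"),
    ("Catenibacterium", "Erysipelotrichaceae", "Firmicutes", 0.5, "e4"),
    ("Bulleidia", "Erysipelotrichaceae", "Firmicutes", 0.3, "e2"),
    ("Holdemania", "Erysipelotrichaceae", "Firmicutes", 0.2, "flat"),
    ("Coprobacillus", "Erysipelotrichaceae", "Firmicutes", 0.2, "down"),
    ("RFN20", "Erysipelotrichaceae", "Firmicutes", 0.1, "e2"),
    ("Eubacterium", "Eubacteriaceae", "Firmicutes", 0.5, "e3"),
    ("Peptococcus", "Peptococcaceae", "Firmicutes", 0.3, "e2"),
    ("Peptostreptococcus", "Peptostreptococcaceae", "Firmicutes", 0.5, "up"),
    ("Mogibacterium", "Mogibacteriaceae", "Firmicutes", 0.3, "e2"),
    ("Staphylococcus", "Staphylococcaceae", "Firmicutes", 0.2, "e1"),
    ("Bacillus", "Bacillaceae", "Firmicutes", 0.1, "e1"),
    (UNKNOWN, UNKNOWN, "Firmicutes", 3.0, "flat"),
    # Bacteroidetes
    (UNKNOWN, "Prevotellaceae", "Bacteroidetes", 0.8, "up"),
    ("Parabacteroides", "Porphyromonadaceae", "Bacteroidetes", 1.2, "e1"),
    ("CF231", "Paraprevotellaceae", "Bacteroidetes", 0.6, "e3"),
    ("YRC22", "Paraprevotellaceae", "Bacteroidetes", 0.4, "e3"),
    ("Paraprevotella", "Paraprevotellaceae", "Bacteroidetes", 0.3, "up"),
    ("Alistipes", "Rikenellaceae", "Bacteroidetes", 0.8, "e1"),
    ("AF12", "Rikenellaceae", "Bacteroidetes", 0.3, "down"),
    ("Odoribacter", "Odoribacteraceae", "Bacteroidetes", 0.3, "e2"),
    ("Butyricimonas", "Odoribacteraceae", "Bacteroidetes", 0.2, "flat"),
    (UNKNOWN, UNKNOWN, "Bacteroidetes", 2.0, "e2"),
    # Proteobacteria
    ("Escherichia", "Enterobacteriaceae", "Proteobacteria", 2.5, "e1"),
    (UNKNOWN, "Enterobacteriaceae", "Proteobacteria", 0.8, "down"),
    ("Sutterella", "Alcaligenaceae", "Proteobacteria", 0.8, "e3"),
    ("Desulfovibrio", "Desulfovibrionaceae", "Proteobacteria", 0.5, "e2"),
    ("Succinivibrio", "Succinivibrionaceae", "Proteobacteria", 0.8, "e4"),
    ("Anaerobiospirillum", "Succinivibrionaceae", "Proteobacteria", 0.2, "up"),
    ("Helicobacter", "Helicobacteraceae", "Proteobacteria", 0.3, "e1"),
    ("Actinobacillus", "Pasteurellaceae", "Proteobacteria", 0.3, "e1"),
    # Spirochaetes
    (UNKNOWN, "Spirochaetaceae", "Spirochaetes", 0.3, "e3"),
    ("Sphaerochaeta", "Sphaerochaetaceae", "Spirochaetes", 0.2, "e3"),
    # Fusobacteria
    ("Fusobacterium", "Fusobacteriaceae", "Fusobacteria", 2.0, "e1"),
    (UNKNOWN, "Fusobacteriaceae", "Fusobacteria", 0.4, "down"),
    # Actinobacteria
    ("Bifidobacterium", "Bifidobacteriaceae", "Actinobacteria", 0.6, "e1"),
    ("Collinsella", "Coriobacteriaceae", "Actinobacteria", 0.6, "e4"),
    ("Corynebacterium", "Corynebacteriaceae", "Actinobacteria", 0.3, "e1"),
    ("Rothia", "Micrococcaceae", "Actinobacteria", 0.1, "e1"),
    ("Actinomyces", "Actinomycetaceae", "Actinobacteria", 0.2, "e2"),
    # unknown phylum (removed by the known-phylum filter downstream)
    (UNKNOWN, UNKNOWN, UNKNOWN, 0.6, "flat"),
    ("SHD-231", UNKNOWN, UNKNOWN, 0.4, "flat"),
]

_CLASS_ORDER_BY_PHYLUM = {
    "Firmicutes": ("Clostridia", "Clostridiales"),
    "Bacteroidetes": ("Bacteroidia", "Bacteroidales"),
    "Proteobacteria": ("Gammaproteobacteria", "Enterobacteriales"),
    "Spirochaetes": ("Spirochaetes", "Spirochaetales"),
    "Fusobacteria": ("Fusobacteriia", "Fusobacteriales"),
    "Actinobacteria": ("Actinobacteria", "Bifidobacteriales"),
    UNKNOWN: (UNKNOWN, UNKNOWN),
}


def _genus_key(genus: str, family: str, phylum: str) -> str:
    """Unique roster key; unknown genera are disambiguated by family (and by
    phylum when the family is itself unknown)."""
    if genus != UNKNOWN:
        return genus
    if family != UNKNOWN:
        return f"{UNKNOWN}.{family}"
    return f"{UNKNOWN}.{UNKNOWN}.{phylum}"


def build_roster() -> pd.DataFrame:
    """Roster table indexed by a unique genus key.

    Columns: genus, family, phylum, class, order, base, tilt (tilt is the
    4-vector across E1..E4; discriminating genera carry their explicit mean
    profile in columns e1..e4 instead).
    """
    rows = []
    for genus, (family, phylum, means) in DISCRIMINATING_GENERA.items():
        rows.append((_genus_key(genus, family, phylum), genus, family, phylum, np.nan, "fixed", means))
    for genus, family, phylum, base, tilt in FILLER_GENERA:
        rows.append((_genus_key(genus, family, phylum), genus, family, phylum, base, tilt, (np.nan,) * 4))
    df = pd.DataFrame(
        rows, columns=["key", "genus", "family", "phylum", "base", "tilt", "means"]
    ).set_index("key")
    if df.index.duplicated().any():
        raise ValueError("duplicate genus keys in roster")
    cls = df["phylum"].map(lambda p: _CLASS_ORDER_BY_PHYLUM[p][0])
    order = df["phylum"].map(lambda p: _CLASS_ORDER_BY_PHYLUM[p][1])
    df.insert(3, "class", cls)
    df.insert(4, "order", order)
    return df


def enterotype_mean_profiles(roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """4 x n_genera matrix of mean compositions (fractions, rows sum to 1).

    Discriminating genera keep their printed means; filler mass is allocated
    per (enterotype, phylum) so each enterotype hits its phylum budget, split
    among fillers proportionally to base weight x tilt.
    """
    roster = build_roster() if roster is None else roster
    profile = pd.DataFrame(0.0, index=["E1", "E2", "E3", "E4"], columns=roster.index)
    fixed = roster["tilt"] == "fixed"
    for key in roster.index[fixed]:
        profile[key] = list(roster.loc[key, "means"])
    for phylum, budgets in PHYLUM_BUDGETS.items():
        in_phy = roster["phylum"] == phylum
        claimed = profile[roster.index[in_phy & fixed]].sum(axis=1)
        fillers = roster.index[in_phy & ~fixed]
        if len(fillers) == 0:
            continue
        for e_idx, e in enumerate(profile.index):
            budget = budgets[e_idx] - claimed.iloc[e_idx]
            if budget <= 0:
                raise ValueError(
                    f"phylum budget for {phylum}/{e} below the fixed-genus mass"
                )
            raw = np.array(
                [roster.loc[k, "base"] * TILTS[roster.loc[k, "tilt"]][e_idx] for k in fillers]
            )
            profile.loc[e, fillers] = budget * raw / raw.sum()
    profile = profile.div(profile.sum(axis=1), axis=0)  # percent -> fraction
    return profile


def otu_expansion(roster: pd.DataFrame | None = None, power: float = 1.3) -> pd.DataFrame:
    """Deterministic genus -> OTU expansion.

    Each genus is split into 5-13 OTUs (count fixed by a stable hash of the
    genus key) with within-genus weights following a power-law rank decay.
    Returns a table indexed by otu_id with columns key (genus key) and weight
    (within-genus fraction).
    """
    import hashlib

    roster = build_roster() if roster is None else roster
    rows = []
    for key in roster.index:
        h = int.from_bytes(hashlib.blake2s(key.encode()).digest()[:4], "little")
        n_otus = 5 + h % 9
        w = 1.0 / np.arange(1, n_otus + 1) ** power
        w /= w.sum()
        for j in range(n_otus):
            rows.append((f"OTU_{h % 100000:05d}_{j:02d}", key, w[j]))
    df = pd.DataFrame(rows, columns=["otu_id", "key", "weight"]).set_index("otu_id")
    if df.index.duplicated().any():  # hash collision guard
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"OTU id collision: {dup}")
    return df
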