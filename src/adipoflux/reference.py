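"""Published reference dataset for primary brown adipocytes.

Mean ± SD rates (nmol·h⁻¹·cm⁻², n = 3 independent experiments) for WT
and Ucp1-KO cultures in four treatment blocks: basal, isoproterenol
(iso), oligomycin (oligo basal) and oligomycin + isoproterenol
(oligo iso). Glycerol, FFA and lactate were measured in the supernatant,
O₂ consumption by plate respirometry, glucose uptake by tracer assay
(absent in the oligo blocks). CO₂, FFA oxidized, FFA re-esterified and
TAG hydrolyzed are the authors' derived values, kept here only as
cross-check targets — this package always recomputes them.

``None`` encodes cells printed as "<0" (negative re-esterification).
"""

from __future__ import annotations

import pandas as pd

MEASURED_QUANTITIES = (
    "glycerol_release",
    "ffa_release",
    "o2_consumption",
    "glucose_uptake",
    "lactate_release",
)

DERIVED_QUANTITIES = (
    "ffa_oxidized",
    "ffa_reesterified",
    "tag_hydrolyzed",
    "co2_production",
)

# (genotype, block) -> quantity -> (mean, sd); None means printed "<0"
PUBLISHED_RATES: dict[tuple[str, str], dict[str, tuple[float | None, float | None]]] = {
    ("UCP1KO", "Basal"): {
        "glycerol_release": (6.0, 1.8),
        "ffa_release": (9.6, 1.8),
        "ffa_oxidized": (1.8, 0.0),
        "ffa_reesterified": (6.4, 4.6),
        "tag_hydrolyzed": (5.9, 1.7),
        "o2_consumption": (44.4, 6.6),
        "co2_production": (27.6, 4.2),
        "glucose_uptake": (2.3, 0.0),
        "lactate_release": (114.6, 15.0),
    },
    ("WT", "Basal"): {
        "glycerol_release": (7.2, 1.8),
        "ffa_release": (15.6, 7.2),
        "ffa_oxidized": (2.4, 0.6),
        "ffa_reesterified": (4.0, 1.8),
        "tag_hydrolyzed": (7.2, 2.3),
        "o2_consumption": (50.4, 19.2),
        "co2_production": (31.2, 12.0),
        "glucose_uptake": (2.2, 0.0),
        "lactate_release": (59.4, 7.2),
    },
    ("UCP1KO", "Iso"): {
        "glycerol_release": (58.2, 9.0),
        "ffa_release": (124.8, 24.0),
        "ffa_oxidized": (6.6, 0.0),
        "ffa_reesterified": (43.7, 4.6),
        "tag_hydrolyzed": (58.4, 8.7),
        "o2_consumption": (151.8, 6.6),
        "co2_production": (94.2, 4.2),
        "glucose_uptake": (3.8, 0.6),
        "lactate_release": (165.6, 24.6),
    },
    ("WT", "Iso"): {
        "glycerol_release": (28.2, 5.4),
        "ffa_release": (66.6, 3.6),
        "ffa_oxidized": (7.2, 0.6),
        "ffa_reesterified": (10.9, 19.3),
        "tag_hydrolyzed": (28.2, 5.1),
        "o2_consumption": (165.6, 10.8),
        "co2_production": (102.6, 6.6),
        "glucose_uptake": (3.5, 0.6),
        "lactate_release": (98.4, 14.4),
    },
    ("UCP1KO", "Oligo basal"): {
        "glycerol_release": (3.0, 2.4),
        "ffa_release": (8.4, 1.8),
        "ffa_oxidized": (0.6, 0.0),
        "ffa_reesterified": (None, None),
        "tag_hydrolyzed": (3.0, 2.2),
        "o2_consumption": (20.4, 4.8),
        "co2_production": (12.6, 3.0),
        "lactate_release": (156.6, 19.2),
    },
    ("WT", "Oligo basal"): {
        "glycerol_release": (4.2, 1.2),
        "ffa_release": (11.4, 6.0),
        "ffa_oxidized": (0.6, 0.0),
        "ffa_reesterified": (0.6, 3.0),
        "tag_hydrolyzed": (4.4, 1.0),
        "o2_consumption": (18.6, 6.6),
        "co2_production": (11.4, 4.2),
        "lactate_release": (102.6, 25.2),
    },
    ("UCP1KO", "Oligo iso"): {
        "glycerol_release": (38.4, 6.6),
        "ffa_release": (123.6, 21.6),
        "ffa_oxidized": (2.4, 0.0),
        "ffa_reesterified": (None, None),
        "tag_hydrolyzed": (38.2, 6.6),
        "o2_consumption": (48.0, 2.4),
        "co2_production": (30.0, 1.2),
        "lactate_release": (181.8, 16.2),
    },
    ("WT", "Oligo iso"): {
        "glycerol_release": (16.2, 3.6),
        "ffa_release": (38.4, 7.2),
        "ffa_oxidized": (6.6, 1.8),
        "ffa_reesterified": (3.9, 4.2),
        "tag_hydrolyzed": (16.3, 4.0),
        "o2_consumption": (152.4, 46.8),
        "co2_production": (94.8, 29.4),
        "lactate_release": (126.6, 3.6),
    },
}


def reference_mean(genotype: str, block: str, quantity: str) -> float:
    """Published mean for one cell of the reference table."""
    mean = PUBLISHED_RATES[(genotype, block)][quantity][0]
    if mean is None:
        raise ValueError(f"{quantity} for ({genotype}, {block}) is printed as '<0'")
    return mean


def reference_frame(measured_only: bool = False) -> pd.DataFrame:
    """Reference table as a tidy DataFrame (genotype, block, quantity, mean, sd)."""
    rows = []
    for (genotype, block), cells in PUBLISHED_RATES.items():
        for quantity, (mean, sd) in cells.items():
            if measured_only and quantity not in MEASURED_QUANTITIES:
                continue
            rows.append(
                {
                    "genotype": genotype,
                    "block": block,
                    "quantity": quantity,
                    "mean": mean,
                    "sd": sd,
                    "below_zero": mean is None,
                }
            )
    return pd.DataFrame(rows)
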