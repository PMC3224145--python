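"""Threshold-trait recoding of adjusted quantitative phenotypes.

Many binary traits are modelled as an underlying liability crossing a
threshold.  Here the quantitative phenotype (adjusted for fixed effects)
is coded affected when it exceeds mean + k·s.d. of the analysed set; the
affected counts of the two duplicate measurements can then be equalised by
reclassifying the nearest-to-threshold excess animals, and the agreement of
the two codings is tabulated as a 2x2 concordance table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiscreteTrait",
    "ConcordanceTable",
    "threshold_code",
    "equalize_affected",
    "concordance_table",
    "drop_discordant",
]


@dataclass
class DiscreteTrait:
    """Affected/unaffected coding with each animal's margin to the threshold."""

    status: pd.Series  # bool, True = affected, indexed by animal
    distance: pd.Series  # signed mm above (+) / below (-) the threshold
    threshold: float
    reclassified: list = field(default_factory=list)

    @property
    def n_affected(self) -> int:
        return int(self.status.sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "status": np.where(self.status, "affected", "unaffected"),
                "distance_to_threshold": self.distance,
                "reclassified": self.status.index.isin(self.reclassified),
            },
            index=self.status.index,
        )


def threshold_code(adjusted: pd.Series, k: float = 1.0) -> DiscreteTrait:
    """Code animals affected when adjusted value > mean + k·s.d.

    Mean and s.d. (n-1 denominator) are computed on the analysed set itself,
    so the affected fraction tracks the upper-tail mass beyond k s.d.
    """
    if len(adjusted) < 2:
        raise ValueError("need at least 2 animals")
    mu = float(adjusted.mean())
    sd = float(adjusted.std(ddof=1))
    if sd == 0:
        raise ValueError("zero phenotypic variance: threshold undefined")
    thr = mu + k * sd
    status = adjusted > thr
    return DiscreteTrait(status=status, distance=adjusted - thr, threshold=thr)


def equalize_affected(
    trait1: DiscreteTrait, trait2: DiscreteTrait
) -> tuple[DiscreteTrait, DiscreteTrait]:
    """Equalise affected counts by reclassifying nearest-threshold animals.

    The trait with more affected animals has its excess affected — those with
    the smallest distance above the threshold, ties broken by animal id —
    reclassified as unaffected until the counts match.  Reclassified animals
    are flagged; the other trait is returned unchanged.
    """
    if set(trait1.status.index) != set(trait2.status.index):
        raise ValueError("both traits must cover the same animals")
    n1, n2 = trait1.n_affected, trait2.n_affected
    if n1 == n2:
        return trait1, trait2
    big, small = (trait1, trait2) if n1 > n2 else (trait2, trait1)
    excess = abs(n1 - n2)
    affected = big.status[big.status].index
    order = sorted(affected, key=lambda a: (big.distance[a], str(a)))
    demoted = order[:excess]
    new_status = big.status.copy()
    new_status[demoted] = False
    adjusted_big = DiscreteTrait(
        status=new_status,
        distance=big.distance,
        threshold=big.threshold,
        reclassified=list(big.reclassified) + list(demoted),
    )
    return (adjusted_big, small) if n1 > n2 else (small, adjusted_big)


@dataclass
class ConcordanceTable:
    """Joint affected/unaffected counts of two codings of the same animals.

    Class labels follow the ++ / +A / A+ / AA convention: '+' unaffected,
    'A' affected, first symbol = trait 1.
    """

    both_unaffected: int
    trait1_only_affected: int
    trait2_only_affected: int
    both_affected: int

    @property
    def n(self) -> int:
        return (
            self.both_unaffected
            + self.trait1_only_affected
            + self.trait2_only_affected
            + self.both_affected
        )

    @property
    def n_discordant(self) -> int:
        return self.trait1_only_affected + self.trait2_only_affected

    @property
    def percent_discordant(self) -> float:
        """Percent of animals coded differently, to one decimal."""
        return round(100.0 * self.n_discordant / self.n, 1)

    def as_dict(self) -> dict:
        return {
            "++": self.both_unaffected,
            "A+": self.trait1_only_affected,
            "+A": self.trait2_only_affected,
            "AA": self.both_affected,
            "percent_discordant": self.percent_discordant,
        }


def concordance_table(trait1: DiscreteTrait, trait2: DiscreteTrait) -> ConcordanceTable:
    """Tabulate joint status classes of two codings over the same animals."""
    ids = trait1.status.index
    if set(ids) != set(trait2.status.index):
        raise ValueError("traits cover different animal sets")
    s1 = trait1.status
    s2 = trait2.status.reindex(ids)
    return ConcordanceTable(
        both_unaffected=int((~s1 & ~s2).sum()),
        trait1_only_affected=int((s1 & ~s2).sum()),
        trait2_only_affected=int((~s1 & s2).sum()),
        both_affected=int((s1 & s2).sum()),
    )


def discrete_phenotype_frame(trait1: DiscreteTrait, trait2: DiscreteTrait) -> pd.DataFrame:
    """Combined per-animal coding table (animal, status1, status2, flags),
    ready to write as the discrete-phenotype CSV."""
    ids = trait1.status.index
    if set(ids) != set(trait2.status.index):
        raise ValueError("traits cover different animal sets")
    s2 = trait2.status.reindex(ids)
    return pd.DataFrame(
        {
            "animal": ids,
            "status1": np.where(trait1.status, "affected", "unaffected"),
            "status2": np.where(s2, "affected", "unaffected"),
            "reclassified1": ids.isin(trait1.reclassified),
            "reclassified2": ids.isin(trait2.reclassified),
            "discordant": (trait1.status != s2).values,
        }
    ).reset_index(drop=True)


def drop_discordant(trait1: DiscreteTrait, trait2: DiscreteTrait) -> list:
    """Ids of concordantly coded animals (the discordant ones removed)."""
    ids = trait1.status.index
    s2 = trait2.status.reindex(ids)
    return list(ids[trait1.status == s2])
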