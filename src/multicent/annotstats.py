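"""Annotation-based statistics on protein subsets.

Proteins carry vitamin-association labels from a 13-class scheme (A, the
eight B vitamins, C, D, E, K), a transcription-regulation flag and a
publication count.  The module compares a protein subset (typically the
detected hubs) with a background set: fat- versus water-soluble vitamin
proportions and transcription-factor proportions by chi-squared tests,
distributions by two-sample Kolmogorov-Smirnov, and per-vitamin enrichment
profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VITAMIN_CLASSES_13 = (
    "A", "B1", "B2", "B3", "B5", "B6", "B7", "B9", "B12", "C", "D", "E", "K",
)
VITAMIN_CLASSES_6 = ("A", "B", "C", "D", "E", "K")

#: Fat-soluble vitamins; all B vitamins and C are water-soluble.
FAT_SOLUBLE = frozenset({"A", "D", "E", "K"})
WATER_SOLUBLE = frozenset(set(VITAMIN_CLASSES_13) - FAT_SOLUBLE)


def read_annotations(source: IO[str] | str) -> pd.DataFrame:
    """Read a TSV annotation table.

    Expected columns: ``accession``, ``vitamins`` (semicolon-separated
    labels), ``is_tf`` (0/1), ``publications`` (integer).
    """
    df = pd.read_csv(source, sep="\t", dtype={"accession": str})
    df = df.set_index("accession")
    df["vitamins"] = [
        frozenset(str(v).split(";")) - {"", "nan"} for v in df["vitamins"]
    ]
    bad = set().union(*df["vitamins"]) - set(VITAMIN_CLASSES_13)
    if bad:
        raise ValueError(f"unknown vitamin labels: {sorted(bad)}")
    df["is_tf"] = df["is_tf"].astype(bool)
    df["publications"] = df["publications"].astype(int)
    if (df["publications"] < 0).any():
        raise ValueError("negative publication counts")
    return df


def write_annotations(annot: pd.DataFrame, sink) -> None:
    out = annot.copy()
    out["vitamins"] = [";".join(sorted(v)) for v in out["vitamins"]]
    out["is_tf"] = out["is_tf"].astype(int)
    out.to_csv(sink, sep="\t", index_label="accession")


def solubility_split(
    annot: pd.DataFrame, ids: Iterable[str]
) -> tuple[int, int]:
    """Count proteins in ``ids`` linked to fat- and to water-soluble vitamins.

    A protein associated with both groups contributes to both counts
    (logged); proteins with no vitamin label are excluded.
    """
    ids = set(ids)
    missing = ids - set(annot.index)
    if missing:
        raise KeyError(f"unannotated protein(s): {sorted(missing)}")
    fat = water = both = 0
    for pid in ids:
        vits = annot.loc[pid, "vitamins"]
        is_fat = bool(vits & FAT_SOLUBLE)
        is_water = bool(vits & WATER_SOLUBLE)
        fat += is_fat
        water += is_water
        both += is_fat and is_water
    if both:
        logger.info("%d protein(s) counted in both solubility groups", both)
    return fat, water


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    pvalue: float
    corrected: bool


def chi2_test(table, correction: bool = True) -> Chi2Result:
    """Pearson chi-squared test on a 2x2 (or r x c) contingency table.

    ``correction`` toggles the Yates continuity correction (meaningful for
    2x2 tables; the conventional default in R is to apply it, so both
    variants are typically reported side by side).
    """
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=correction)
    return Chi2Result(statistic=float(stat), df=int(dof), pvalue=float(p),
                      corrected=correction)


_KS_ALTERNATIVES = {
    "two-sided": "two-sided",
    "one-sided-greater": "greater",
    "one-sided-less": "less",
}


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    alternative: str


def ks_two_sample(x, y, alternative: str = "two-sided") -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (maximum ECDF gap)."""
    if alternative not in _KS_ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative=_KS_ALTERNATIVES[alternative],
                         method="asymp")
    return KSResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    alternative=alternative)


def _to_scheme(vits: frozenset, scheme: str) -> set[str]:
    if scheme == "13-class":
        return set(vits)
    if scheme == "6-class":
        return {"B" if v.startswith("B") else v for v in vits}
    raise ValueError(f"unknown scheme {scheme!r}; use '13-class' or '6-class'")


def enrichment_profile(
    annot: pd.DataFrame,
    subset: Iterable[str],
    scheme: str = "13-class",
) -> pd.DataFrame:
    """Per-vitamin association proportions for a subset vs. the background.

    A protein associated with several vitamins counts once in each class, so
    per-group proportions may sum to more than one.  The background is the
    whole annotation table.
    """
    classes = VITAMIN_CLASSES_13 if scheme == "13-class" else VITAMIN_CLASSES_6
    subset = set(subset)
    missing = subset - set(annot.index)
    if missing:
        raise KeyError(f"unannotated protein(s): {sorted(missing)}")

    def proportions(ids: Sequence[str]) -> pd.Series:
        counts = {c: 0 for c in classes}
        for pid in ids:
            for c in _to_scheme(annot.loc[pid, "vitamins"], scheme):
                counts[c] += 1
        n = max(len(ids), 1)
        return pd.Series({c: counts[c] / n for c in classes})

    return pd.DataFrame(
        {
            "subset": proportions(sorted(subset)),
            "background": proportions(list(annot.index)),
        }
    )
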