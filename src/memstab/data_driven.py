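"""Abundance-weighted rank scoring derived from variant stability data.

The training input is a set of alanine-scan style stability records
(relative stability as percent of wild-type).  Records above 140% of
wild-type stability count as stabilising, below 80% as destabilising.  For
every bioinformatic factor (wild-type amino acid, topology class, binned
conservation, binned lipid-contact, binned helix-contact, binned disorder)
each level's association with stabilisation is measured as a frequency
normalised to that level's total observation count — removing the skew
toward abundant levels such as alanine.  Levels are then ranked twice:

* by stabilising weight, descending — rank ``r`` earns ``L + 1 - r`` points;
* by destabilising weight, descending — rank ``r`` earns ``r`` points
  (the level *least* associated with destabilisation earns the most).

The combined level score is the sum.  With 20 amino-acid levels, a residue
type ranked 4th for stabilising association and last for destabilising
association scores (20 + 1 - 4) + 20 = 37.

A query position's final score is the product of its factors' combined
scores; scores are reported as percent of the best position in the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ProteinTarget, StabilityRecord, default_substitution

log = logging.getLogger("memstab")

STAB_THRESHOLD = 140.0   # percent of wild-type; strictly above = stabilising
DESTAB_THRESHOLD = 80.0  # percent of wild-type; strictly below = destabilising

FACTORS = (
    "amino_acid",
    "topology",
    "conservation_bin",
    "lipid_contact_bin",
    "helix_contact_bin",
    "disorder_bin",
)

#: The five factors used for ranking before disorder prediction was added.
CORE_FACTORS = FACTORS[:5]

CONSERVATION_BIN_WIDTH = 10.0  # percent; ten bins over 0-100
CONTACT_N_BINS = 5             # equal bins over [0, 1]


def classify_stability(relative_stability: float,
                       stab_threshold: float = STAB_THRESHOLD,
                       destab_threshold: float = DESTAB_THRESHOLD) -> str:
    if relative_stability < 0:
        raise ValueError(f"negative relative stability {relative_stability}")
    if relative_stability > stab_threshold:
        return "stabilising"
    if relative_stability < destab_threshold:
        return "destabilising"
    return "neutral"


def classify_stability_records(records,
                               stab_threshold: float = STAB_THRESHOLD,
                               destab_threshold: float = DESTAB_THRESHOLD,
                               ) -> list[str]:
    """Class label per record; both thresholds are strict inequalities."""
    labels = [
        classify_stability(r.relative_stability, stab_threshold, destab_threshold)
        for r in records
    ]
    counts = pd.Series(labels).value_counts()
    log.info("classified %d records: %s", len(labels), counts.to_dict())
    return labels


def conservation_bin(value: float) -> str:
    """Ten 10-percent-wide bins; 100% folds into the top bin."""
    if not 0 <= value <= 100:
        raise ValueError(f"conservation {value} outside [0, 100]")
    idx = min(int(value // CONSERVATION_BIN_WIDTH), 9)
    lo = int(idx * CONSERVATION_BIN_WIDTH)
    return f"{lo:02d}-{lo + 10}"


def contact_bin(value: float) -> str:
    """Five equal bins over [0, 1]; 1.0 folds into the top bin."""
    if not 0 <= value <= 1:
        raise ValueError(f"contact/disorder score {value} outside [0, 1]")
    idx = min(int(value * CONTACT_N_BINS), CONTACT_N_BINS - 1)
    return f"{idx / CONTACT_N_BINS:.1f}-{(idx + 1) / CONTACT_N_BINS:.1f}"


def factor_level(factor: str, *, wt_aa: str, feature_row) -> str:
    """Level of ``factor`` for a residue with the given feature row."""
    if factor == "amino_acid":
        return wt_aa
    if factor == "topology":
        return feature_row["topology_class"]
    if factor == "conservation_bin":
        return conservation_bin(feature_row["conservation"])
    if factor == "lipid_contact_bin":
        return contact_bin(feature_row["lipid_contact"])
    if factor == "helix_contact_bin":
        return contact_bin(feature_row["helix_contact"])
    if factor == "disorder_bin":
        return contact_bin(feature_row["disorder"])
    raise ValueError(f"unknown factor {factor!r}")


@dataclass
class FactorWeights:
    """Per-level stabilising/destabilising frequencies for one factor."""

    factor: str
    table: pd.DataFrame  # index: level; columns: stab_weight, destab_weight, n_observations

    def __post_init__(self):
        if len(self.table) < 2:
            raise ValueError(
                f"factor {self.factor!r}: {len(self.table)} observed level(s); "
                "at least 2 are needed to rank"
            )


def derive_factor_weights(records, labels, features_by_target, factor,
                          ) -> FactorWeights:
    """Abundance-weighted association of each factor level with stability.

    stab_weight(level)  = stabilising records at level / records at level,
    destab_weight(level) likewise.  Neutral records enter the denominator
    only.  ``features_by_target`` maps target_id to its feature table.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels differ in length")
    rows = []
    for rec, lab in zip(records, labels):
        feats = features_by_target[rec.target_id]
        frow = feats.iloc[rec.variant.position - 1]
        level = factor_level(factor, wt_aa=rec.variant.wt_aa, feature_row=frow)
        rows.append((level, lab))
    df = pd.DataFrame(rows, columns=["level", "label"])
    grouped = df.groupby("level")["label"]
    out = pd.DataFrame(
        {
            "stab_weight": grouped.apply(lambda s: (s == "stabilising").mean()),
            "destab_weight": grouped.apply(lambda s: (s == "destabilising").mean()),
            "n_observations": grouped.size(),
        }
    )
    return FactorWeights(factor, out)


def weights_to_scores(weights: FactorWeights) -> pd.DataFrame:
    """Turn per-level weights into the 1..L rank scores for one factor.

    Ties in weight are broken by observation count (more observations
    first), then by level name — deterministic and logged.
    """
    t = weights.table
    L = len(t)

    def ranked(weight_col):
        order = (
            t.assign(_lvl=t.index.astype(str))
            .sort_values(by=[weight_col, "n_observations", "_lvl"],
                         ascending=[False, False, True], kind="mergesort")
        )
        return {level: r + 1 for r, level in enumerate(order.index)}

    stab_rank = ranked("stab_weight")
    destab_rank = ranked("destab_weight")
    out = pd.DataFrame(
        {
            "factor": weights.factor,
            "level": list(t.index),
            "stab_score": [L + 1 - stab_rank[lvl] for lvl in t.index],
            "destab_score": [destab_rank[lvl] for lvl in t.index],
        }
    )
    out["combined"] = out["stab_score"] + out["destab_score"]
    return out.sort_values("combined", ascending=False).reset_index(drop=True)


class ScoringMatrix:
    """Per-factor, per-level combined rank scores; TSV round-trippable."""

    def __init__(self, table: pd.DataFrame):
        required = {"factor", "level", "stab_score", "destab_score", "combined"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"scoring matrix missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self._lookup = {
            (row.factor, str(row.level)): int(row.combined)
            for row in table.itertuples()
        }
        self._median = {
            f: float(np.median(g["combined"]))
            for f, g in table.groupby("factor")
        }

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.table["factor"]))

    def combined_score(self, factor: str, level: str) -> float:
        """Combined score of a level; unseen levels fall back to the factor median.

        Small training sets will miss rare residues, so an unseen level is
        scored at the factor's median combined score with a warning rather
        than failing the whole query.
        """
        if factor not in self._median:
            raise KeyError(f"factor {factor!r} not in scoring matrix")
        key = (factor, str(level))
        if key in self._lookup:
            return float(self._lookup[key])
        log.warning(
            "scoring matrix: level %r unseen for factor %s; using factor "
            "median %.1f", level, factor, self._median[factor],
        )
        return self._median[factor]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScoringMatrix":
        return cls(pd.read_csv(path, sep="\t"))


def load_synthetic_default_matrix() -> ScoringMatrix:
    """Packaged scoring matrix derived from the synthetic stability fixture.

    Synthetic: built from the seeded fixture generator (seed 0), not from
    any measured receptor stability dataset.  Intended for smoke tests and
    worked examples; train on real stability data for production use.
    """
    from importlib.resources import files

    path = files("memstab").joinpath("data/synthetic_default_matrix.tsv")
    with path.open() as fh:
        return ScoringMatrix(pd.read_csv(fh, sep="\t"))


def derive_scoring_matrix(records: list[StabilityRecord],
                          features_by_target: dict[str, pd.DataFrame],
                          stab_threshold: float = STAB_THRESHOLD,
                          destab_threshold: float = DESTAB_THRESHOLD,
                          factors=FACTORS) -> ScoringMatrix:
    """Full training path: classify records, weight, rank, assemble matrix."""
    labels = classify_stability_records(records, stab_threshold, destab_threshold)
    parts = []
    for factor in factors:
        w = derive_factor_weights(records, labels, features_by_target, factor)
        parts.append(weights_to_scores(w))
    return ScoringMatrix(pd.concat(parts, ignore_index=True))


def score_positions(target: ProteinTarget, features: pd.DataFrame,
                    matrix: ScoringMatrix, include_disorder: bool = True,
                    ) -> pd.DataFrame:
    """Product-of-factor-scores ranking of every position in the target.

    Five factor scores (amino acid, topology, conservation, lipid contact,
    helix contact) are multiplied; with ``include_disorder`` a sixth
    disorder score joins the product.  Output is sorted by score descending,
    normalised to percent of the best position, with the default candidate
    substitution (alanine, leucine for native alanine) attached.
    """
    if len(features) != len(target):
        raise ValueError(
            f"feature table has {len(features)} rows for a {len(target)}-residue target"
        )
    factors = FACTORS if include_disorder else CORE_FACTORS
    rows = []
    for pos in range(1, len(target) + 1):
        wt = target.residue(pos)
        frow = features.iloc[pos - 1]
        scores = {
            f: matrix.combined_score(f, factor_level(f, wt_aa=wt, feature_row=frow))
            for f in factors
        }
        final = float(np.prod(list(scores.values())))
        rows.append({"position": pos, "wt_aa": wt,
                     "mut_aa": default_substitution(wt),
                     **{f"score_{f}": v for f, v in scores.items()},
                     "final_score": final})
    df = pd.DataFrame(rows)
    df["normalised_score"] = 100.0 * df["final_score"] / df["final_score"].max()
    df = df.sort_values(["final_score", "position"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)
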