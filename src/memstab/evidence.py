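"""Deep-sequence and model-based evidence streams.

Both streams end in a ``CandidateList``: ranked variant candidates with a
raw score, a score normalised to percent of the best candidate, and dense
ranks 1..n.  The deep-sequence stream proposes substitutions toward
residues favoured in a large alignment ("odd-one-out" replacement); the
model-based stream ingests per-model ΔΔG-of-unfolding tables from in
silico saturation mutagenesis.

Sign convention, used throughout: **negative ΔΔG = stabilising**.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CANONICAL_AA, Variant

log = logging.getLogger("memstab")

MODULE_TAGS = ("deep_sequence", "model_based", "data_driven")
NORMALISED_CUTOFF = 70.0  # percent of best score; candidates must exceed it


@dataclass
class CandidateList:
    """Ranked candidates from one selection module."""

    module: str
    table: pd.DataFrame  # columns: position, wt_aa, mut_aa, raw_score,
    #                                normalised_score, rank

    def __post_init__(self):
        if self.module not in MODULE_TAGS:
            raise ValueError(f"unknown module tag {self.module!r}")
        t = self.table.reset_index(drop=True)
        if len(t):
            if list(t["rank"]) != list(range(1, len(t) + 1)):
                raise ValueError(f"{self.module}: ranks are not dense 1..n")
            if (np.diff(t["normalised_score"]) > 1e-9).any():
                raise ValueError(
                    f"{self.module}: normalised score increases with rank"
                )
            pairs = list(zip(t["position"], t["mut_aa"]))
            if len(set(pairs)) != len(pairs):
                raise ValueError(f"{self.module}: duplicate (position, substitution)")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def variants(self) -> list[Variant]:
        return [Variant(int(r.position), r.wt_aa, r.mut_aa)
                for r in self.table.itertuples()]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "module", self.module)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "CandidateList":
        df = pd.read_csv(path, sep="\t")
        modules = df["module"].unique()
        if len(modules) != 1:
            raise ValueError(f"{path}: expected one module tag, found {modules}")
        return cls(str(modules[0]), df.drop(columns="module"))


def _finalise(module: str, rows: list[dict]) -> CandidateList:
    """Sort by raw score descending (ties: position ascending), rank, normalise."""
    df = pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa", "raw_score"])
    df = df.sort_values(["raw_score", "position"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    if len(df):
        df["normalised_score"] = 100.0 * df["raw_score"] / df["raw_score"].iloc[0]
    else:
        df["normalised_score"] = pd.Series(dtype=float)
    df["rank"] = range(1, len(df) + 1)
    return CandidateList(module, df)


# ---------------------------------------------------------------------------
# Deep-sequence stream
# ---------------------------------------------------------------------------

def consensus_effect_table(msa: list[str], query_index: int = 0,
                           pseudocount: float = 1.0) -> pd.DataFrame:
    """Independent-sites substitution effects from alignment column counts.

    effect(pos, x) = ln[(count(x) + pc) / (count(wt) + pc)] at the column
    aligned to query position ``pos``; positive means residue ``x`` is used
    more often than the query's own residue at that site.  Columns that are
    gaps in the query are dropped; gaps in other rows do not count as
    residues.
    """
    if len(msa) < 2:
        raise ValueError(f"alignment depth {len(msa)} < 2")
    widths = {len(s) for s in msa}
    if len(widths) != 1:
        raise ValueError("alignment rows differ in length")
    query = msa[query_index].upper()
    rows = []
    pos = 0
    for col_idx, wt in enumerate(query):
        if wt in "-.":
            continue
        pos += 1
        if wt not in CANONICAL_AA:
            raise ValueError(
                f"query has non-canonical residue {wt!r} at column {col_idx}"
            )
        column = [s[col_idx].upper() for s in msa]
        counts = {aa: 0 for aa in CANONICAL_AA}
        for c in column:
            if c in counts:
                counts[c] += 1
        wt_count = counts[wt]
        for aa in CANONICAL_AA:
            if aa == wt:
                continue
            num = counts[aa] + pseudocount
            den = wt_count + pseudocount
            if num <= 0 or den <= 0:
                continue  # only possible with pseudocount 0 and empty counts
            rows.append({"position": pos, "wt_aa": wt, "mut_aa": aa,
                         "effect": math.log(num / den)})
    return pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa", "effect"])


def select_deep_sequence(effects: pd.DataFrame,
                         cutoff_percent: float = NORMALISED_CUTOFF,
                         ) -> CandidateList:
    """Best favourable substitution per site, kept above the normalised cutoff.

    Only strictly positive effects are considered; per site the argmax
    substitution is taken; kept scores are normalised to percent of the
    best site and entries above ``cutoff_percent`` survive.
    """
    positive = effects[effects["effect"] > 0]
    if positive.empty:
        log.warning("deep-sequence: no favourable substitutions; empty list")
        return _finalise("deep_sequence", [])
    rows = []
    for pos, group in positive.groupby("position"):
        best = group.sort_values(["effect", "mut_aa"],
                                 ascending=[False, True]).iloc[0]
        rows.append({"position": int(pos), "wt_aa": best["wt_aa"],
                     "mut_aa": best["mut_aa"], "raw_score": float(best["effect"])})
    full = _finalise("deep_sequence", rows)
    kept = full.table[full.table["normalised_score"] > cutoff_percent].copy()
    kept["rank"] = range(1, len(kept) + 1)
    log.info("deep-sequence: %d sites favourable, %d above %.0f%% cutoff",
             len(full), len(kept), cutoff_percent)
    return CandidateList("deep_sequence", kept)


# ---------------------------------------------------------------------------
# Model-based stream
# ---------------------------------------------------------------------------

@dataclass
class DdgTable:
    """Per-model ΔΔG table from in silico mutagenesis (negative = stabilising)."""

    model_id: str
    table: pd.DataFrame  # columns: position, wt_aa, mut_aa, ddg
    model_unfolding_energy: float = math.nan

    def __post_init__(self):
        t = self.table
        required = {"position", "wt_aa", "mut_aa", "ddg"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"model {self.model_id}: missing columns {sorted(missing)}")
        if not np.isfinite(t["ddg"]).all():
            raise ValueError(f"model {self.model_id}: non-finite ΔΔG values")

    @classmethod
    def from_tsv(cls, path, model_id=None, model_unfolding_energy=math.nan):
        df = pd.read_csv(path, sep="\t")
        if "model_unfolding_energy" in df.columns:
            model_unfolding_energy = float(df["model_unfolding_energy"].iloc[0])
            df = df.drop(columns="model_unfolding_energy")
        return cls(model_id or str(path), df, model_unfolding_energy)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["model_unfolding_energy"] = self.model_unfolding_energy
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def aggregate_alascan(tables: list[DdgTable],
                      cutoff_percent: float = NORMALISED_CUTOFF,
                      ) -> pd.DataFrame:
    """Average alanine-substitution ΔΔG per position across models.

    Positions are ordered by the number of models in which the alanine
    substitution is stabilising (more models first — this damps bias from
    any single poorly modelled site), then by mean ΔΔG ascending (most
    negative first).  The normalised score is percent of the most negative
    mean among stabilising positions; positions above ``cutoff_percent``
    carry ``passes=True`` into the position-scan stage.
    """
    if not tables:
        raise ValueError("no ΔΔG tables supplied")
    per_model = []
    for t in tables:
        ala = t.table[t.table["mut_aa"] == "A"]
        if ala.empty:
            raise ValueError(f"model {t.model_id}: no alanine-substitution rows")
        per_model.append(ala.set_index("position")["ddg"])
    common = set(per_model[0].index)
    for s in per_model[1:]:
        common &= set(s.index)
    union = set().union(*(set(s.index) for s in per_model))
    if common != union:
        log.warning("models disagree on positions; using intersection of %d "
                    "(union %d)", len(common), len(union))
    positions = sorted(common)
    stacked = np.array([[s.loc[p] for p in positions] for s in per_model])
    mean_ddg = stacked.mean(axis=0)
    n_models_improved = (stacked < 0).sum(axis=0)
    df = pd.DataFrame({"position": positions, "mean_ddg": mean_ddg,
                       "n_models_improved": n_models_improved})
    df = df.sort_values(["n_models_improved", "mean_ddg", "position"],
                        ascending=[False, True, True],
                        kind="mergesort").reset_index(drop=True)
    best = df["mean_ddg"].min()
    if best < 0:
        norm = np.where(df["mean_ddg"] < 0, 100.0 * df["mean_ddg"] / best, 0.0)
    else:
        norm = np.zeros(len(df))
    df["normalised_score"] = norm
    df["passes"] = df["normalised_score"] > cutoff_percent
    log.info("alanine-scan aggregation: %d positions, %d above %.0f%% cutoff",
             len(df), int(df["passes"].sum()), cutoff_percent)
    return df


def best_model(tables: list[DdgTable]) -> DdgTable:
    """Model with the lowest unfolding free energy after minimisation."""
    if any(math.isnan(t.model_unfolding_energy) for t in tables):
        raise ValueError("model unfolding energies required to pick the best model")
    return min(tables, key=lambda t: t.model_unfolding_energy)


def select_model_based(passing_positions, scan: DdgTable) -> CandidateList:
    """Best substitution per passing position from the full position scan.

    Per position the most negative ΔΔG substitution wins; positions where
    every substitution is destabilising are dropped with a warning.
    Ranking is by that ΔΔG ascending (raw score = −ΔΔG so the shared
    percent-normalisation applies).
    """
    rows = []
    by_pos = dict(tuple(scan.table.groupby("position")))
    for pos in sorted(passing_positions):
        if pos not in by_pos:
            raise ValueError(f"position {pos} missing from position scan "
                             f"of model {scan.model_id}")
        group = by_pos[pos]
        best = group.sort_values(["ddg", "mut_aa"], ascending=[True, True]).iloc[0]
        if best["ddg"] >= 0:
            log.warning("position %d: no stabilising substitution in scan; dropped",
                        pos)
            continue
        rows.append({"position": int(pos), "wt_aa": best["wt_aa"],
                     "mut_aa": best["mut_aa"], "raw_score": float(-best["ddg"])})
    return _finalise("model_based", rows)
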