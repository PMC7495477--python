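"""Seeded generators for every input class the pipeline consumes.

The generators emulate the statistical structure of the training and test
data the method was built on, without redistributing any measured dataset:

* an alanine-scan style stability compendium of roughly 2,000 records over
  three receptor-sized targets measured in one to three conformational
  states, with ~7.6% stabilising and ~48.5% destabilising records overall;
* planted factor effects mirroring the trends the scoring matrix is meant
  to recover: substitutions of G, T, A, Q, E and H (in descending order)
  enriched among stabilisers, I, Y, W, D, C and V among destabilisers,
  transmembrane-helix positions stabiliser-enriched, cytosolic-helix
  positions destabiliser-enriched, conservation 50-60% stabiliser-enriched
  and 80-90% destabiliser-enriched;
* redundant multiple-sequence alignments with planted "odd-one-out" query
  positions; multi-model ΔΔG tables with planted stabilising sites; noisy
  four-parameter-logistic melt curves; and circular plasmids carrying the
  reverse-translated coding sequence.

Every generator is fully determined by the seed in its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CANONICAL_AA, ProteinTarget, StabilityRecord, Variant, \
    default_substitution
from .data_driven import conservation_bin, contact_bin
from .evidence import DdgTable
from .melt import TEN_TEMP_GRID, MeltCurve, four_pl
from .primers import CODON_TABLE, ECOLI_USAGE

#: Planted amino-acid preferences, strongest first.
PLANTED_STAB_AA = ("G", "T", "A", "Q", "E", "H")
PLANTED_DESTAB_AA = ("I", "Y", "W", "D", "C", "V")

BASE_STAB_RATE = 0.076    # stabilising records per residue sampled at random
BASE_DESTAB_RATE = 0.485  # destabilising records per residue

_AA_STAB_MULT = {aa: m for aa, m in
                 zip(PLANTED_STAB_AA, (3.2, 2.8, 2.4, 2.0, 1.75, 1.5))}
_AA_DESTAB_MULT = {aa: m for aa, m in
                   zip(PLANTED_DESTAB_AA, (1.9, 1.8, 1.7, 1.6, 1.5, 1.4))}
_TOPOLOGY_STAB_MULT = {"TM_helix": 1.8}
_TOPOLOGY_DESTAB_MULT = {"cytosolic_helix": 1.6}
_CONS_STAB_MULT = {"50-60": 1.8}
_CONS_DESTAB_MULT = {"80-90": 1.5}


@dataclass
class FixtureSpec:
    """Knobs for all generators; the seed fully determines every output."""

    seed: int = 0
    n_records: int = 2000
    msa_depth: int = 500
    n_odd_positions: int = 10
    n_models: int = 3
    n_planted_sites: int = 12
    ddg_noise_sd: float = 1.0
    melt_noise_sd: float = 0.03
    plasmid_length: int = 3000
    gc_content: float = 0.5

    # conformational states per generated target, mirroring a compendium of
    # three receptors measured in 3, 2 and 1 states
    states_per_target: tuple = (("apo", "agonist", "antagonist"),
                                ("apo", "agonist"), ("apo",))


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


# ---------------------------------------------------------------------------
# Stability compendium with planted factor effects
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))

def _random_topology(rng, length: int) -> list[str]:
    """Alternating helix/loop architecture typical of a polytopic protein."""
    out: list[str] = []
    inside = True
    while len(out) < length:
        loop = "cytosolic_loop" if inside else "extracellular_loop"
        helix = rng.choice(["TM_helix", "TM_helix", "TM_helix",
                            "cytosolic_helix" if inside
                            else "extracellular_helix", "reentrant"])
        out.extend([loop] * int(rng.integers(4, 12)))
        out.extend([str(helix)] * int(rng.integers(18, 26)))
        inside = not inside
    return out[:length]


def _features_for(rng, target: ProteinTarget) -> pd.DataFrame:
    L = len(target)
    return pd.DataFrame({
        "position": np.arange(1, L + 1),
        "topology_class": _random_topology(rng, L),
        "conservation": rng.uniform(0, 100, L),
        "lipid_contact": rng.uniform(0, 1, L),
        "helix_contact": rng.uniform(0, 1, L),
        "disorder": rng.uniform(0, 1, L),
    })


def _class_probabilities(wt_aa: str, feature_row) -> tuple[float, float]:
    """(p_stab, p_destab) for one residue under the planted effects."""
    w_s = BASE_STAB_RATE * _AA_STAB_MULT.get(wt_aa, 1.0)
    w_d = BASE_DESTAB_RATE * _AA_DESTAB_MULT.get(wt_aa, 1.0)
    topo = feature_row["topology_class"]
    w_s *= _TOPOLOGY_STAB_MULT.get(topo, 1.0)
    w_d *= _TOPOLOGY_DESTAB_MULT.get(topo, 1.0)
    cbin = conservation_bin(feature_row["conservation"])
    w_s *= _CONS_STAB_MULT.get(cbin, 1.0)
    w_d *= _CONS_DESTAB_MULT.get(cbin, 1.0)
    w_n = 1.0 - BASE_STAB_RATE - BASE_DESTAB_RATE
    total = w_s + w_d + w_n
    return w_s / total, w_d / total


def generate_stability_dataset(spec: FixtureSpec):
    """Stability records + feature tables + per-(target, position) truth.

    Returns ``(records, features_by_target, truth_by_target, targets)``
    where truth maps position to its class label in the target's first
    state (the label the enrichment evaluation scores against).
    """
    rng = _rng(spec, 1)
    n_state_sets = sum(len(s) for s in spec.states_per_target)
    base_len = spec.n_records // n_state_sets
    records: list[StabilityRecord] = []
    features_by_target: dict[str, pd.DataFrame] = {}
    truth_by_target: dict[str, dict[int, str]] = {}
    targets = []
    for t_idx, states in enumerate(spec.states_per_target):
        length = base_len  # equal-length targets; any remainder is dropped
        tid = f"SYN{t_idx + 1}"
        target = ProteinTarget(tid, _random_sequence(rng, length))
        feats = _features_for(rng, target)
        features_by_target[tid] = feats
        targets.append(target)
        truth: dict[int, str] = {}
        for pos in range(1, length + 1):
            wt = target.residue(pos)
            p_s, p_d = _class_probabilities(wt, feats.iloc[pos - 1])
            for s_idx, state in enumerate(states):
                u = rng.random()
                if u < p_s:
                    label = "stabilising"
                    rel = rng.uniform(141.0, 220.0)
                elif u < p_s + p_d:
                    label = "destabilising"
                    rel = rng.uniform(10.0, 79.0)
                else:
                    label = "neutral"
                    rel = rng.uniform(81.0, 139.0)
                mut = default_substitution(wt)
                records.append(StabilityRecord(
                    tid, Variant(pos, wt, mut), rel, state))
                if s_idx == 0:
                    truth[pos] = label
        truth_by_target[tid] = truth
    return records, features_by_target, truth_by_target, targets


# ---------------------------------------------------------------------------
# Multiple sequence alignments with planted odd-one-out positions
# ---------------------------------------------------------------------------

def generate_msa(spec: FixtureSpec, length: int = 120):
    """Redundant MSA plus query; returns (rows, odd_positions, preferred).

    ``odd_positions`` are 1-based query positions where the query carries a
    residue rare in its column; ``preferred`` maps those positions to the
    column consensus residue the adapter should propose.
    """
    rng = _rng(spec, 2)
    aas = list(CANONICAL_AA)
    odd = sorted(rng.choice(np.arange(1, length + 1),
                            size=min(spec.n_odd_positions, length),
                            replace=False).tolist())
    consensus = rng.choice(aas, size=length)
    columns = []
    query = []
    preferred = {}
    for pos in range(1, length + 1):
        cons = str(consensus[pos - 1])
        others = [a for a in aas if a != cons]
        # column: consensus-dominated with a thin tail of other residues
        freqs = np.full(20, 0.3 / 19)
        freqs[aas.index(cons)] = 0.7
        col = rng.choice(aas, size=spec.msa_depth - 1, p=freqs)
        if pos in odd:
            q = str(rng.choice(others))
            preferred[pos] = cons
        else:
            q = cons
        query.append(q)
        columns.append(col)
    rows = ["".join(query)]
    for depth in range(spec.msa_depth - 1):
        rows.append("".join(str(columns[i][depth]) for i in range(length)))
    return rows, odd, preferred


# ---------------------------------------------------------------------------
# Multi-model ΔΔG tables with planted stabilising sites
# ---------------------------------------------------------------------------

def generate_ddg_tables(spec: FixtureSpec, target: ProteinTarget):
    """Per-model alanine-scan tables, a full scan for the best model, and
    the planted stabilising site list."""
    rng = _rng(spec, 3)
    L = len(target)
    positions = np.arange(1, L + 1)
    mutable = [p for p in positions if target.residue(p) != "A"]
    planted = sorted(rng.choice(mutable, size=min(spec.n_planted_sites,
                                                  len(mutable)),
                                replace=False).tolist())
    base = rng.normal(1.0, 0.7, size=L)  # mildly destabilising background
    for p in planted:
        base[p - 1] = rng.normal(-2.0, 0.3)
    tables = []
    energies = rng.uniform(80.0, 140.0, size=spec.n_models)
    for m in range(spec.n_models):
        noise = rng.normal(0.0, spec.ddg_noise_sd, size=L)
        rows = [{"position": int(p), "wt_aa": target.residue(int(p)),
                 "mut_aa": "A", "ddg": float(base[p - 1] + noise[p - 1])}
                for p in mutable]
        tables.append(DdgTable(f"model{m + 1}", pd.DataFrame(rows),
                               float(energies[m])))
    # full position scan for the best model: alanine keeps its ala-scan
    # value; other substitutions scatter around the site's base effect
    best_idx = int(np.argmin(energies))
    scan_rows = []
    for p in mutable:
        wt = target.residue(int(p))
        site_base = base[p - 1]
        for aa in CANONICAL_AA:
            if aa == wt:
                continue
            ddg = site_base + rng.normal(0.0, 0.4)
            scan_rows.append({"position": int(p), "wt_aa": wt,
                              "mut_aa": aa, "ddg": float(ddg)})
    scan = DdgTable(f"model{best_idx + 1}", pd.DataFrame(scan_rows),
                    float(energies[best_idx]))
    return tables, scan, planted


# ---------------------------------------------------------------------------
# Melt curves and plasmids
# ---------------------------------------------------------------------------

def generate_melt_curves(spec: FixtureSpec, true_tm: float = 49.3,
                         slope: float = 0.5, n_repeats: int = 3,
                         grid=TEN_TEMP_GRID, construct: str = "WT",
                         top: float = 1.0, bottom: float = 0.0,
                         ) -> list[MeltCurve]:
    """Noisy 4PL melt curves on the given temperature grid."""
    rng = _rng(spec, 4)
    temps = np.asarray(grid, dtype=float)
    curves = []
    for rep in range(n_repeats):
        clean = four_pl(temps, true_tm, slope, top, bottom)
        noisy = clean + rng.normal(0.0, spec.melt_noise_sd, size=len(temps))
        ice = 1000.0  # arbitrary gel-intensity scale; fits normalise it away
        curves.append(MeltCurve(construct, f"rep{rep + 1}",
                                temps, noisy * ice, ice))
    return curves


def generate_plasmid(spec: FixtureSpec, target: ProteinTarget):
    """Circular plasmid with the reverse-translated CDS; returns
    ``(plasmid, cds_offset)`` with the offset 0-based."""
    rng = _rng(spec, 5)
    cds = []
    for aa in target.sequence:
        codons = CODON_TABLE[aa]
        weights = np.array([ECOLI_USAGE.get(c, 0.01) for c in codons])
        cds.append(str(rng.choice(codons, p=weights / weights.sum())))
    cds = "".join(cds)
    backbone_len = spec.plasmid_length - len(cds)
    if backbone_len < 100:
        raise ValueError("plasmid_length too short for the CDS plus backbone")
    p_gc = spec.gc_content / 2
    p_at = (1 - spec.gc_content) / 2
    backbone = "".join(rng.choice(list("ACGT"), size=backbone_len,
                                  p=[p_at, p_gc, p_gc, p_at]))
    offset = int(rng.integers(0, backbone_len))
    plasmid = backbone[:offset] + cds + backbone[offset:]
    return plasmid, offset
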