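"""Domain types and I/O shared by every stage of the pipeline.

Residue numbering is 1-based everywhere a position is exposed to the user,
matching the conventional variant label (e.g. ``G130A`` = glycine 130 to
alanine).  Conversion to 0-based indexing happens only inside sequence
lookups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("memstab")

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Topology vocabulary used by per-residue feature tables.  Readers map
#: tool-specific labels onto these six classes via TOPOLOGY_ALIASES.
TOPOLOGY_CLASSES = (
    "TM_helix",
    "cytosolic_helix",
    "cytosolic_loop",
    "extracellular_helix",
    "extracellular_loop",
    "reentrant",
)

TOPOLOGY_ALIASES = {
    "tm": "TM_helix",
    "tmh": "TM_helix",
    "tm_helix": "TM_helix",
    "transmembrane": "TM_helix",
    "cyt_helix": "cytosolic_helix",
    "cytosolic_helix": "cytosolic_helix",
    "cyt_loop": "cytosolic_loop",
    "cytosolic_loop": "cytosolic_loop",
    "inside": "cytosolic_loop",
    "ext_helix": "extracellular_helix",
    "extracellular_helix": "extracellular_helix",
    "ext_loop": "extracellular_loop",
    "extracellular_loop": "extracellular_loop",
    "outside": "extracellular_loop",
    "reentrant": "reentrant",
    "re-entrant": "reentrant",
}

_FEATURE_COLUMNS = (
    "position",
    "topology_class",
    "conservation",
    "lipid_contact",
    "helix_contact",
    "disorder",
)


class VariantParseError(ValueError):
    """Raised for malformed or impossible variant labels."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single amino-acid substitution, e.g. ``Variant(130, 'G', 'A')``."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.position < 1:
            raise VariantParseError(
                f"residue positions are 1-based; got {self.position}"
            )
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in CANONICAL_AA:
                raise VariantParseError(f"non-canonical amino acid {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise VariantParseError(
                f"wild-type and substituted residue are both {self.wt_aa!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_variant_label(label: str) -> Variant:
    """Parse a ``<wt><position><mut>`` label such as ``F20Y``.

    Round-trips: ``parse_variant_label(v.label) == v`` for any variant.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise VariantParseError(f"malformed variant label {label!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    try:
        return Variant(pos, wt, mut)
    except VariantParseError as exc:
        raise VariantParseError(f"invalid variant label {label!r}: {exc}") from exc


def default_substitution(wt_aa: str) -> str:
    """Alanine, or leucine when the native residue is already alanine."""
    if wt_aa not in CANONICAL_AA:
        raise ValueError(f"non-canonical amino acid {wt_aa!r}")
    return "L" if wt_aa == "A" else "A"


@dataclass
class ProteinTarget:
    """Target protein: sequence plus positions barred from mutagenesis."""

    id: str
    sequence: str
    excluded_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"target {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - set(CANONICAL_AA))
        if bad:
            raise ValueError(
                f"target {self.id!r}: non-canonical letters {bad} in sequence "
                "(only the 20 standard amino acids are accepted)"
            )
        self.excluded_positions = frozenset(int(p) for p in self.excluded_positions)
        out = [p for p in self.excluded_positions if not 1 <= p <= len(self)]
        if out:
            raise ValueError(
                f"target {self.id!r}: excluded positions {sorted(out)} outside "
                f"1..{len(self)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self):
            raise IndexError(
                f"position {position} outside 1..{len(self)} of target {self.id!r}"
            )
        return self.sequence[position - 1]


def validate_against_target(variant: Variant, target: ProteinTarget) -> Variant:
    """Check that the variant's wild-type letter matches the target sequence."""
    actual = target.residue(variant.position)
    if actual != variant.wt_aa:
        raise ValueError(
            f"variant {variant.label}: target {target.id!r} has {actual!r} at "
            f"position {variant.position}, not {variant.wt_aa!r}"
        )
    return variant


@dataclass(frozen=True)
class StabilityRecord:
    """One measured variant: relative stability as percent of wild-type."""

    target_id: str
    variant: Variant
    relative_stability: float
    state: str = "apo"

    def __post_init__(self):
        if self.relative_stability < 0:
            raise ValueError(
                f"{self.target_id} {self.variant.label}: negative relative "
                f"stability {self.relative_stability}"
            )


# ---------------------------------------------------------------------------
# File readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path) -> tuple[str, str]:
    """Read the first record of a FASTA file as ``(id, sequence)``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def load_target(path, excluded_positions=()) -> ProteinTarget:
    rid, seq = read_fasta(path)
    target = ProteinTarget(rid, seq, frozenset(excluded_positions))
    log.info("loaded target %s: %d residues, %d excluded",
             rid, len(target), len(target.excluded_positions))
    return target


def load_feature_table(path, target: ProteinTarget | None = None) -> pd.DataFrame:
    """Load a per-residue feature TSV and validate it against the target.

    Required columns: position, topology_class, conservation (percent,
    0-100), lipid_contact, helix_contact, disorder (each in [0, 1]).
    Positions must be exactly 1..L with no gaps; anything else fails loudly
    rather than being silently reindexed.  Continuous features on other
    scales are min-max rescaled into range and the rescaling is logged.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path}: missing columns {missing}")
    df = df[list(_FEATURE_COLUMNS)].copy()
    df["position"] = df["position"].astype(int)
    df = df.sort_values("position").reset_index(drop=True)
    positions = df["position"].to_numpy()
    expected_len = len(target) if target is not None else len(df)
    if len(df) != expected_len or (positions != range(1, expected_len + 1)).any():
        raise ValueError(
            f"feature table {path}: positions must be exactly 1..{expected_len} "
            "(one contiguous row per residue); refusing to reindex"
        )
    df["topology_class"] = [
        _canonical_topology(t, path) for t in df["topology_class"]
    ]
    if (df["conservation"] < 0).any() or (df["conservation"] > 100).any():
        raise ValueError(f"feature table {path}: conservation outside [0, 100]")
    for col in ("lipid_contact", "helix_contact", "disorder"):
        lo, hi = df[col].min(), df[col].max()
        if lo < 0 or hi > 1:
            df[col] = (df[col] - lo) / (hi - lo)
            log.warning(
                "feature table %s: column %s rescaled from [%.3g, %.3g] to [0, 1]",
                path, col, lo, hi,
            )
    return df


def _canonical_topology(label: str, source) -> str:
    if label in TOPOLOGY_CLASSES:
        return label
    key = str(label).strip().lower()
    if key in TOPOLOGY_ALIASES:
        return TOPOLOGY_ALIASES[key]
    raise ValueError(f"feature table {source}: unknown topology class {label!r}")


def load_stability_records(path) -> list[StabilityRecord]:
    """Read variant stability TSV: target_id, variant, relative_stability[, state]."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"target_id", "variant", "relative_stability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stability table {path}: missing columns {sorted(missing)}")
    if "state" not in df.columns:
        df["state"] = "apo"
    records = [
        StabilityRecord(
            str(row.target_id),
            parse_variant_label(str(row.variant)),
            float(row.relative_stability),
            str(row.state),
        )
        for row in df.itertuples()
    ]
    keys = [(r.target_id, r.variant, r.state) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError(
            f"stability table {path}: duplicate (target, variant, state) rows"
        )
    log.info("loaded %d stability records from %s", len(records), path)
    return records


def write_stability_records(records, path) -> None:
    pd.DataFrame(
        {
            "target_id": [r.target_id for r in records],
            "variant": [r.variant.label for r in records],
            "relative_stability": [r.relative_stability for r in records],
            "state": [r.state for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_exclusion_file(path) -> frozenset[int]:
    """Newline-delimited positions or dash ranges (e.g. ``57-60``)."""
    out: set[int] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if "-" in line:
                a, b = line.split("-", 1)
                lo, hi = int(a), int(b)
                if hi < lo:
                    raise ValueError(f"exclusion range {line!r}: end before start")
                out.update(range(lo, hi + 1))
            else:
                out.add(int(line))
    return frozenset(out)
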