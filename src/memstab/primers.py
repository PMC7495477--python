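"""Inverse-PCR mutagenic primer design with nearest-neighbour Tm.

Whole-plasmid amplification with back-to-back, non-overlapping primers:
the forward primer carries the mutant codon with at least 10 matched bases
on each side of the mismatch; the reverse primer binds the opposite strand
immediately upstream, so blunt-end ligation of the product reconstitutes
the plasmid with exactly the intended codon replaced.

Melting temperatures come from the nearest-neighbour model,

    Tm = (dH_init + sum dH_stack) * 1000 / (dS_init + sum dS_stack + R ln Cp)
         - 273.15  [degrees C]

with dH in kcal/mol, dS in cal/(K mol), R = 1.987 cal/(K mol) and Cp the
primer concentration (default 0.5 uM, the PCR recipe concentration; Cp is
used directly).  The stack table is the unified oligonucleotide parameter
set, whose reference state is 1 M NaCl; the packaged parameterisation
applies the standard entropic monovalent-salt correction

    dS = dS[1M] + 0.368 * (N - 1) * ln [Na+]

at a default [Na+] of 50 mM (typical PCR buffer).  Without it a
minimum-length primer (10-nt flanks around the codon) already melts above
70 degC on a GC-balanced template and the grow-to-window iteration could
never operate.  Mismatched bases contribute no stack terms: both stacks
flanking a mismatch are skipped; the salt term follows primer length, not
pairing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .core import Variant

log = logging.getLogger("memstab")

R_GAS = 1.987  # cal / (K mol)
DEFAULT_PRIMER_CONC = 5e-7  # mol/L (0.5 uM)

#: Unified nearest-neighbour parameters: dinucleotide -> (dH kcal/mol,
#: dS cal/(K mol)).  Symmetric under reverse complement.
NN_STACKS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

#: Duplex-initiation terms per terminal base pair.
NN_INIT = {
    "G": (0.1, -2.8), "C": (0.1, -2.8),
    "A": (2.3, 4.1), "T": (2.3, 4.1),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TM_WINDOW = (65.0, 70.0)   # degrees C, forward-primer target window
ANNEAL_TARGET = 62.0       # degrees C, shared annealing temperature goal
MIN_FLANK = 10             # matched bases required either side of the mismatch
MIN_PRIMER_LEN = 18


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ThermoParams:
    stacks: dict = field(default_factory=lambda: dict(NN_STACKS))
    init: dict = field(default_factory=lambda: dict(NN_INIT))
    primer_conc: float = DEFAULT_PRIMER_CONC
    salt_molar: float = 0.05  # monovalent cation concentration, mol/L

    def __post_init__(self):
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.stacks)
        if missing:
            raise ValueError(f"stack table missing dinucleotides {sorted(missing)}")
        if self.primer_conc <= 0:
            raise ValueError("primer concentration must be positive")
        if self.salt_molar <= 0:
            raise ValueError("salt concentration must be positive")


def nn_melting_temperature(primer: str, params: ThermoParams | None = None,
                           mismatch_positions: frozenset[int] = frozenset(),
                           ) -> float:
    """Nearest-neighbour Tm in degrees C of a primer annealed to its template.

    ``mismatch_positions`` are 0-based indices of primer bases that do not
    pair with the template; their flanking stacks are skipped.
    """
    params = params or ThermoParams()
    primer = primer.upper()
    if len(primer) < 8:
        raise ValueError(f"primer too short for the model ({len(primer)} nt)")
    bad = set(primer) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous bases {sorted(bad)} in primer")
    dh = params.init[primer[0]][0] + params.init[primer[-1]][0]
    ds = params.init[primer[0]][1] + params.init[primer[-1]][1]
    for i in range(len(primer) - 1):
        if i in mismatch_positions or (i + 1) in mismatch_positions:
            continue
        h, s = params.stacks[primer[i:i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(primer) - 1) * math.log(params.salt_molar)
    denom = ds + R_GAS * math.log(params.primer_conc)
    if denom >= 0:
        raise ValueError("non-physical denominator in Tm calculation "
                         f"(dS total {ds:.1f}, primer {primer})")
    return dh * 1000.0 / denom - 273.15


# ---------------------------------------------------------------------------
# Codon choice
# ---------------------------------------------------------------------------

CODON_TABLE = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

AA_BY_CODON = {c: aa for aa, codons in CODON_TABLE.items() for c in codons}

#: E. coli K-12 codon usage (fraction per amino acid); tie-break table for
#: codon choice.  Host-specific tables can be passed in instead.
ECOLI_USAGE = {
    "GCT": 0.16, "GCC": 0.27, "GCA": 0.21, "GCG": 0.36,
    "TGT": 0.45, "TGC": 0.55, "GAT": 0.63, "GAC": 0.37,
    "GAA": 0.69, "GAG": 0.31, "TTT": 0.57, "TTC": 0.43,
    "GGT": 0.34, "GGC": 0.40, "GGA": 0.11, "GGG": 0.15,
    "CAT": 0.57, "CAC": 0.43, "ATT": 0.51, "ATC": 0.42, "ATA": 0.07,
    "AAA": 0.77, "AAG": 0.23,
    "TTA": 0.13, "TTG": 0.13, "CTT": 0.10, "CTC": 0.10, "CTA": 0.04,
    "CTG": 0.50, "ATG": 1.00, "AAT": 0.45, "AAC": 0.55,
    "CCT": 0.16, "CCC": 0.12, "CCA": 0.19, "CCG": 0.53,
    "CAA": 0.35, "CAG": 0.65,
    "CGT": 0.38, "CGC": 0.40, "CGA": 0.06, "CGG": 0.10,
    "AGA": 0.04, "AGG": 0.02,
    "TCT": 0.15, "TCC": 0.15, "TCA": 0.12, "TCG": 0.15,
    "AGT": 0.15, "AGC": 0.28,
    "ACT": 0.17, "ACC": 0.44, "ACA": 0.13, "ACG": 0.27,
    "GTT": 0.26, "GTC": 0.22, "GTA": 0.15, "GTG": 0.37,
    "TGG": 1.00, "TAT": 0.57, "TAC": 0.43,
}


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3].upper()
        if codon not in AA_BY_CODON:
            raise ValueError(f"cannot translate codon {codon!r} at nt {i + 1}")
        out.append(AA_BY_CODON[codon])
    return "".join(out)


def choose_mutant_codon(wt_codon: str, target_aa: str,
                        usage_table: dict | None = None) -> str:
    """Codon of ``target_aa`` with fewest edits from the wild-type codon.

    Ties go to the higher usage frequency in the host table, then
    alphabetical order.
    """
    usage = usage_table or ECOLI_USAGE
    wt_codon = wt_codon.upper()
    if wt_codon not in AA_BY_CODON:
        raise ValueError(f"{wt_codon!r} is not a sense codon")
    if target_aa not in CODON_TABLE:
        raise ValueError(f"unsupported target amino acid {target_aa!r}")
    if AA_BY_CODON[wt_codon] == target_aa:
        raise ValueError(f"codon {wt_codon} already encodes {target_aa}")

    def key(codon):
        edits = sum(a != b for a, b in zip(codon, wt_codon))
        return (edits, -usage.get(codon, 0.0), codon)

    return min(CODON_TABLE[target_aa], key=key)


# ---------------------------------------------------------------------------
# Primer pair design
# ---------------------------------------------------------------------------

@dataclass
class PrimerPair:
    variant: Variant
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    annealing_recommendation: float
    forward_start: int  # 0-based template index of the forward primer 5' base
    reverse_start: int  # 0-based template index where the reverse footprint starts


class PrimerDesignError(RuntimeError):
    pass


def _circular_slice(seq: str, start: int, length: int) -> str:
    """Slice a circular sequence; indices wrap modulo the length."""
    n = len(seq)
    start %= n
    if length > n:
        raise ValueError("slice longer than the plasmid")
    if start + length <= n:
        return seq[start:start + length]
    return seq[start:] + seq[:start + length - n]


def design_primer_pair(plasmid: str, cds_offset: int, variant: Variant,
                       params: ThermoParams | None = None,
                       usage_table: dict | None = None) -> PrimerPair:
    """Design a non-overlapping inverse-PCR primer pair for one variant.

    ``plasmid`` is the circular template top strand; ``cds_offset`` is the
    0-based index of the first CDS base.  The forward primer is seeded with
    10 nt either side of the mutant codon and grown or trimmed at its 3'
    end until its Tm enters the 65-70 degC window (closest achievable
    otherwise); the reverse primer starts immediately 5' of the forward
    footprint on the opposite strand and is grown at its 3' end to match
    the forward Tm; a joint refinement then nudges both 3' ends so the
    shared annealing recommendation lands as close to 62 degC as the window
    and the 10-nt flank floor allow.
    """
    params = params or ThermoParams()
    plasmid = plasmid.upper()
    n = len(plasmid)
    codon_tpl_start = (cds_offset + 3 * (variant.position - 1)) % n
    wt_codon = _circular_slice(plasmid, codon_tpl_start, 3)
    if AA_BY_CODON.get(wt_codon) != variant.wt_aa:
        raise PrimerDesignError(
            f"{variant.label}: template codon {wt_codon} at CDS position "
            f"{variant.position} encodes {AA_BY_CODON.get(wt_codon)!r}, "
            f"not {variant.wt_aa!r}"
        )
    mut_codon = choose_mutant_codon(wt_codon, variant.mut_aa, usage_table)
    mism_in_codon = [i for i in range(3) if wt_codon[i] != mut_codon[i]]
    first_mm, last_mm = mism_in_codon[0], mism_in_codon[-1]

    def flank5_offset(flank5: int) -> int:
        # matched bases 5' of the *first mismatched base*: bases before the
        # codon plus any matched codon bases preceding the mismatch
        return max(flank5 - first_mm, 0)

    def flank3_offset(flank3: int) -> int:
        return max(flank3 - (2 - last_mm), 0)

    max_len = n // 2 - 2  # keep forward + reverse footprints apart on the circle

    def build_forward(flank3: int):
        seq5 = _circular_slice(
            plasmid, codon_tpl_start - flank5_offset(MIN_FLANK),
            flank5_offset(MIN_FLANK))
        seq3 = _circular_slice(plasmid, codon_tpl_start + 3, flank3_offset(flank3))
        primer = seq5 + mut_codon + seq3
        mms = frozenset(len(seq5) + i for i in mism_in_codon)
        start = (codon_tpl_start - flank5_offset(MIN_FLANK)) % n
        return primer, mms, start

    def fwd_tm(flank3: int) -> float:
        primer, mms, _ = build_forward(flank3)
        return nn_melting_temperature(primer, params, mms)

    lo, hi = TM_WINDOW
    flank3 = MIN_FLANK
    tm = fwd_tm(flank3)
    while tm < lo:
        flank3 += 1
        primer_len = flank5_offset(MIN_FLANK) + 3 + flank3_offset(flank3)
        if primer_len > max_len:
            raise PrimerDesignError(
                f"{variant.label}: cannot reach {lo} degC forward Tm "
                f"(reached {tm:.1f} degC at {primer_len} nt)")
        tm = fwd_tm(flank3)
    while tm > hi and flank3 > MIN_FLANK:
        new_tm = fwd_tm(flank3 - 1)
        if new_tm < lo:
            # window skipped between single-base steps: keep closest
            if abs(new_tm - (lo + hi) / 2) < abs(tm - (lo + hi) / 2):
                flank3 -= 1
                tm = new_tm
            break
        flank3 -= 1
        tm = new_tm

    def build_reverse(length: int, fwd_start: int):
        tpl_start = (fwd_start - length) % n
        footprint = _circular_slice(plasmid, tpl_start, length)
        return revcomp(footprint), tpl_start

    def rev_tm(length: int, fwd_start: int) -> float:
        seq, _ = build_reverse(length, fwd_start)
        return nn_melting_temperature(seq, params)

    def match_reverse(fwd_start: int, target_tm: float) -> int:
        length = MIN_PRIMER_LEN
        best_len, best_gap = length, abs(rev_tm(length, fwd_start) - target_tm)
        while length < max_len:
            length += 1
            gap = abs(rev_tm(length, fwd_start) - target_tm)
            if gap < best_gap:
                best_len, best_gap = length, gap
            elif rev_tm(length, fwd_start) > target_tm + 5:
                break
        return best_len

    # joint refinement: scan feasible forward 3' flanks, matching a reverse
    # to each, and keep the pair whose annealing lands nearest 62 degC
    best = None
    for f3 in range(MIN_FLANK, flank3 + 6):
        primer, mms, fstart = build_forward(f3)
        if len(primer) > max_len:
            break
        t_f = nn_melting_temperature(primer, params, mms)
        if not (lo <= t_f <= hi):
            continue
        rlen = match_reverse(fstart, t_f)
        rseq, rstart = build_reverse(rlen, fstart)
        t_r = nn_melting_temperature(rseq, params)
        anneal = min(ANNEAL_TARGET, min(t_f, t_r) - 3.0)
        score = (abs(min(t_f, t_r) - 3.0 - ANNEAL_TARGET), abs(t_f - t_r))
        if best is None or score < best[0]:
            best = (score, primer, mms, fstart, rseq, rstart, t_f, t_r, anneal)
    if best is None:
        # no flank reached the window; fall back to the closest-achievable length
        primer, mms, fstart = build_forward(flank3)
        t_f = nn_melting_temperature(primer, params, mms)
        rlen = match_reverse(fstart, t_f)
        rseq, rstart = build_reverse(rlen, fstart)
        t_r = nn_melting_temperature(rseq, params)
        anneal = min(ANNEAL_TARGET, min(t_f, t_r) - 3.0)
        best = (None, primer, mms, fstart, rseq, rstart, t_f, t_r, anneal)

    _, fwd, mms, fstart, rseq, rstart, t_f, t_r, anneal = best
    if len(fwd) < MIN_PRIMER_LEN or len(rseq) < MIN_PRIMER_LEN:
        raise PrimerDesignError(f"{variant.label}: primer below "
                                f"{MIN_PRIMER_LEN} nt floor")
    pair = PrimerPair(variant, fwd, rseq, t_f, t_r, anneal, fstart, rstart)
    _assert_reconstruction(plasmid, pair, wt_codon, mut_codon, codon_tpl_start)
    return pair


def reconstruct_plasmid(plasmid: str, pair: PrimerPair) -> str:
    """In-silico blunt ligation of the inverse-PCR amplicon.

    The amplicon runs from the forward primer's 5' end around the circle to
    the reverse primer's 5' end (which is the reverse complement of the
    template immediately upstream of the forward footprint).  Ligation
    rejoins the two blunt ends, yielding the template with the forward
    footprint replaced by the forward primer sequence.
    """
    n = len(plasmid)
    fstart, flen = pair.forward_start, len(pair.forward)
    rstart, rlen = pair.reverse_start, len(pair.reverse)
    if (rstart + rlen) % n != fstart % n:
        raise PrimerDesignError("reverse primer does not abut the forward primer")
    rebuilt = list(plasmid)
    for i, base in enumerate(pair.forward):
        rebuilt[(fstart + i) % n] = base
    # reverse primer must match the template exactly (no mismatch carried)
    if revcomp(pair.reverse) != _circular_slice(plasmid, rstart, rlen):
        raise PrimerDesignError("reverse primer mismatches its template footprint")
    return "".join(rebuilt)


def _assert_reconstruction(plasmid, pair, wt_codon, mut_codon, codon_tpl_start):
    n = len(plasmid)
    expected = list(plasmid)
    for i, base in enumerate(mut_codon):
        expected[(codon_tpl_start + i) % n] = base
    rebuilt = reconstruct_plasmid(plasmid, pair)
    if rebuilt != "".join(expected):
        raise PrimerDesignError(
            f"{pair.variant.label}: ligated amplicon does not reconstruct the "
            "intended mutant plasmid")
    # non-overlap: footprints [rstart, rstart+rlen) and [fstart, fstart+flen)
    occupied = set()
    for i in range(len(pair.forward)):
        occupied.add((pair.forward_start + i) % n)
    for i in range(len(pair.reverse)):
        idx = (pair.reverse_start + i) % n
        if idx in occupied:
            raise PrimerDesignError(f"{pair.variant.label}: primers overlap")
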