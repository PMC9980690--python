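"""Reconstruction of double-stranded CpG methylation from hairpin reads.

A hairpin-bisulfite read carries both strands of one DNA molecule: the
top arm, a UMI-barcoded linker, then the bottom strand read 5'->3'.
Folding the read about the linker and reverse-complementing the right
arm puts the bottom strand into top-strand coordinates, where the only
legitimate disagreements between the arms are the two conversion
signatures: a converted top cytosine (top T vs bottom-complement C) and
a converted bottom cytosine (top G vs bottom-complement A).  Arm
realignment therefore uses an asymmetric substitution matrix that scores
those two pairs as matches, with affine gaps absorbing PCR slippage.

Per reference CpG, the dyad call combines the top-strand base at the C
position (C = methylated, T = unmethylated) with the bottom-complement
base at the G position (G = methylated, A = unmethylated): both
methylated -> M, both unmethylated -> U, exactly one -> H.  Gaps,
unexpected bases, or unmappable columns give the ambiguous state '.',
which is excluded from all counts.

Linker cytosines are known to be unmethylated, so the fraction that
survives conversion estimates the failed-conversion rate; these
conversion-control tallies ride along on every molecule record.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._util import revcomp

__all__ = [
    "FoldConfig",
    "HairpinRead",
    "StrandAlignment",
    "MoleculeRecord",
    "find_linker",
    "fold_and_align",
    "call_dyads",
    "dedup_umi",
    "tally_counts",
    "fold_reads",
]

logger = logging.getLogger(__name__)

AMBIGUOUS = "."


@dataclass(frozen=True)
class FoldConfig:
    """Tunable parameters of the folding stage."""

    max_mismatch: int = 2        # linker search budget (edits, bisulfite-aware)
    min_arm_length: int = 20     # shorter arms are discarded
    min_identity: float = 0.8    # arm-alignment identity below this -> chimera
    match_score: float = 1.0
    mismatch_score: float = -1.0
    open_gap_score: float = -3.0
    extend_gap_score: float = -1.0


@dataclass
class HairpinRead:
    read_id: str
    sequence: str
    linker_span: tuple[int, int] | None = None  # 0-based half-open
    umi: str | None = None
    control_c_total: int = 0
    control_c_unconverted: int = 0

    def __post_init__(self) -> None:
        if self.linker_span is not None:
            s, e = self.linker_span
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"invalid linker span {self.linker_span}")


@dataclass
class StrandAlignment:
    """Top arm aligned against the reverse-complemented bottom arm."""

    top_arm: str
    bottom_arm_complemented: str
    aligned_columns: list[tuple[str, str]]  # '-' marks a gap
    score: float
    identity: float  # fraction of columns concordant under bisulfite-aware scoring


@dataclass
class MoleculeRecord:
    sample_id: str
    umi: str
    dyad_states: tuple[str, ...]  # M / U / H / '.' per reference CpG
    control_c_total: int = 0
    control_c_unconverted: int = 0

    def __post_init__(self) -> None:
        if self.control_c_unconverted > self.control_c_total:
            raise ValueError("unconverted control count exceeds total")


def _bisulfite_matrix(config: FoldConfig, extra_pairs: tuple[tuple[str, str], ...]):
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == "N" or b == "N":
                m[a, b] = 0.0
            else:
                m[a, b] = config.match_score if a == b else config.mismatch_score
    for a, b in extra_pairs:
        m[a, b] = config.match_score
    return m


def _aligner(config: FoldConfig, extra_pairs) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="global")
    al.substitution_matrix = _bisulfite_matrix(config, extra_pairs)
    al.open_gap_score = config.open_gap_score
    al.extend_gap_score = config.extend_gap_score
    return al


_LINKER_EQUALITIES = [("C", "T")] + [("N", b) for b in "ACGT"]


def find_linker(
    read: str, linker: str, max_mismatch: int = 2
) -> tuple[tuple[int, int], str, int, int] | None:
    """Locate the linker in a read, bisulfite-tolerantly.

    The linker template carries an N-run marking the UMI slot; linker C
    positions match read C or T (conversion must not break detection).
    Best (lowest-edit) hit wins, leftmost on ties.  Returns
    (span, umi, control_c_total, control_c_unconverted) or None when no
    hit is within max_mismatch edits.

    Control tallies count linker-template C positions aligned to a read
    base: a retained C is an unconverted (failed-conversion) event, a T
    is a converted one; other bases are ignored.
    """
    if not linker:
        raise ValueError("linker must be nonempty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be nonnegative")
    res = edlib.align(
        linker, read, mode="HW", task="path", additionalEqualities=_LINKER_EQUALITIES
    )
    if res["editDistance"] < 0 or res["editDistance"] > max_mismatch:
        return None
    start, end_incl = min(res["locations"], key=lambda t: t[0])
    span = (start, end_incl + 1)
    # walk the cigar: map linker positions onto read positions
    qpos, tpos = 0, start
    umi_chars: list[str] = []
    ctrl_total = ctrl_unconv = 0
    for length, op in _parse_cigar(res["cigar"]):
        for _ in range(length):
            if op in "=XM":
                if linker[qpos] == "N":
                    umi_chars.append(read[tpos])
                elif linker[qpos] == "C":
                    ctrl_total += 1
                    if read[tpos] == "C":
                        ctrl_unconv += 1
                qpos += 1
                tpos += 1
            elif op == "I":  # linker base absent from read
                qpos += 1
            elif op == "D":  # extra read base
                tpos += 1
    return span, "".join(umi_chars), ctrl_total, ctrl_unconv


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def fold_and_align(read: HairpinRead, config: FoldConfig = FoldConfig()) -> StrandAlignment:
    """Fold a linker-located read and realign its two strands.

    The right arm is reverse-complemented into top-strand coordinates
    and globally aligned to the top arm under the bisulfite-aware
    asymmetric matrix (top T vs bottom C and top G vs bottom A score as
    matches).  Raises ValueError if either arm is shorter than
    config.min_arm_length.
    """
    if read.linker_span is None:
        raise ValueError("read has no located linker; run find_linker first")
    s, e = read.linker_span
    top = read.sequence[:s]
    bottom_rc = revcomp(read.sequence[e:])
    if len(top) < config.min_arm_length or len(bottom_rc) < config.min_arm_length:
        raise ValueError(
            f"arm below minimum length {config.min_arm_length} "
            f"(top {len(top)}, bottom {len(bottom_rc)})"
        )
    aligner = _aligner(config, extra_pairs=(("T", "C"), ("G", "A")))
    aln = aligner.align(top, bottom_rc)[0]
    gapped_top, gapped_bottom = str(aln[0]), str(aln[1])
    columns = list(zip(gapped_top, gapped_bottom))
    matrix = aligner.substitution_matrix
    n_match = sum(
        1
        for a, b in columns
        if a != "-" and b != "-" and matrix[a, b] > 0
    )
    identity = n_match / len(columns) if columns else 0.0
    return StrandAlignment(
        top_arm=top,
        bottom_arm_complemented=bottom_rc,
        aligned_columns=columns,
        score=float(aln.score),
        identity=identity,
    )


def _map_to_reference(arm: str, reference: str, config: FoldConfig) -> dict[int, int]:
    """reference index -> arm index, via bisulfite-aware global alignment."""
    aligner = _aligner(config, extra_pairs=(("C", "T"), ("G", "A")))
    aln = aligner.align(reference, arm)[0]
    gapped_ref, gapped_arm = str(aln[0]), str(aln[1])
    mapping: dict[int, int] = {}
    ri = ai = 0
    for rc, ac in zip(gapped_ref, gapped_arm):
        if rc != "-" and ac != "-":
            mapping[ri] = ai
        if rc != "-":
            ri += 1
        if ac != "-":
            ai += 1
    return mapping


def call_dyads(
    aln: StrandAlignment,
    reference: str,
    cpg_positions,
    config: FoldConfig = FoldConfig(),
) -> tuple[str, ...]:
    """Classify each reference CpG dyad from a folded alignment.

    The top arm is anchored to the reference (tolerating converted Cs
    and slippage indels); dyad calls then read the top base at the CpG
    C position and the bottom-complement base at the G position through
    the arm alignment.  Anything unexpected is the ambiguous state '.'.
    """
    ref_to_top = _map_to_reference(aln.top_arm, reference, config)
    # top-arm index -> column index in the strand alignment
    top_to_col: dict[int, int] = {}
    ti = 0
    for ci, (a, _) in enumerate(aln.aligned_columns):
        if a != "-":
            top_to_col[ti] = ci
            ti += 1
    states: list[str] = []
    for p in cpg_positions:
        if reference[p : p + 2] != "CG":
            raise ValueError(f"reference position {p} is not a CpG")
        top_i = ref_to_top.get(p)
        top_base = aln.top_arm[top_i] if top_i is not None else None
        if top_base == "C":
            top_meth = True
        elif top_base == "T":
            top_meth = False
        else:
            states.append(AMBIGUOUS)
            continue
        g_i = ref_to_top.get(p + 1)
        col = top_to_col.get(g_i) if g_i is not None else None
        bottom_base = aln.aligned_columns[col][1] if col is not None else None
        if bottom_base == "G":
            bottom_meth = True
        elif bottom_base == "A":
            bottom_meth = False
        else:
            states.append(AMBIGUOUS)
            continue
        if top_meth and bottom_meth:
            states.append("M")
        elif not top_meth and not bottom_meth:
            states.append("U")
        else:
            states.append("H")
    return tuple(states)


def dedup_umi(molecules) -> list[MoleculeRecord]:
    """Collapse PCR duplicates to one record per (sample_id, UMI).

    Conflicting duplicates are resolved per site by majority among
    informative states; ties (including all-ambiguous) give '.'.
    Conversion-control tallies are summed over duplicates.  Idempotent
    and independent of input order.
    """
    grouped: dict[tuple[str, str], list[MoleculeRecord]] = defaultdict(list)
    for rec in molecules:
        grouped[(rec.sample_id, rec.umi)].append(rec)
    out: list[MoleculeRecord] = []
    for (sample_id, umi) in sorted(grouped):
        recs = grouped[(sample_id, umi)]
        n_sites = len(recs[0].dyad_states)
        if any(len(r.dyad_states) != n_sites for r in recs):
            raise ValueError(f"inconsistent dyad count for {sample_id}/{umi}")
        states: list[str] = []
        for site in range(n_sites):
            votes = Counter(
                r.dyad_states[site] for r in recs if r.dyad_states[site] != AMBIGUOUS
            )
            if not votes:
                states.append(AMBIGUOUS)
                continue
            ranked = votes.most_common()
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                states.append(AMBIGUOUS)
            else:
                states.append(ranked[0][0])
        out.append(
            MoleculeRecord(
                sample_id=sample_id,
                umi=umi,
                dyad_states=tuple(states),
                control_c_total=sum(r.control_c_total for r in recs),
                control_c_unconverted=sum(r.control_c_unconverted for r in recs),
            )
        )
    return out


def tally_counts(molecules) -> tuple[pd.DataFrame, float]:
    """Per-individual dyad counts and the pooled failed-conversion rate.

    Returns a DataFrame with columns sample_id, M, U, H, n_control,
    n_unconverted (one row per individual; individuals with zero
    informative dyads are excluded with a warning) and the pooled
    control rate n_unconverted / n_control over the whole run (nan when
    no controls were seen).
    """
    per: dict[str, dict[str, float]] = {}
    for rec in molecules:
        row = per.setdefault(
            rec.sample_id,
            {"M": 0, "U": 0, "H": 0, "n_control": 0, "n_unconverted": 0},
        )
        for s in rec.dyad_states:
            if s in ("M", "U", "H"):
                row[s] += 1
        row["n_control"] += rec.control_c_total
        row["n_unconverted"] += rec.control_c_unconverted
    rows = []
    for sample_id in sorted(per):
        row = per[sample_id]
        if row["M"] + row["U"] + row["H"] == 0:
            logger.warning(
                "sample %s has zero informative dyads; excluded", sample_id
            )
            continue
        rows.append({"sample_id": sample_id, **row})
    df = pd.DataFrame(
        rows, columns=["sample_id", "M", "U", "H", "n_control", "n_unconverted"]
    )
    total_ctrl = int(df["n_control"].sum()) if len(df) else 0
    rate = float(df["n_unconverted"].sum() / total_ctrl) if total_ctrl else float("nan")
    return df, rate


def _sample_id_from_read_id(read_id: str) -> str:
    return read_id.split("|", 1)[0]


def fold_reads(
    reads,
    linker: str,
    reference: str,
    cpg_positions,
    config: FoldConfig = FoldConfig(),
) -> tuple[list[MoleculeRecord], Counter]:
    """Run the full folding stage over (read_id, sequence) pairs.

    Returns deduplicated molecule records plus a Counter of per-read QC
    reason codes ('ok', 'no_linker', 'short_arm', 'low_identity').
    """
    qc: Counter = Counter()
    records: list[MoleculeRecord] = []
    for read_id, seq in reads:
        hit = find_linker(seq, linker, config.max_mismatch)
        if hit is None:
            qc["no_linker"] += 1
            logger.debug("read %s: linker not found", read_id)
            continue
        span, umi, ctrl_total, ctrl_unconv = hit
        read = HairpinRead(read_id, seq, linker_span=span, umi=umi)
        try:
            aln = fold_and_align(read, config)
        except ValueError:
            qc["short_arm"] += 1
            continue
        if aln.identity < config.min_identity:
            qc["low_identity"] += 1
            logger.debug(
                "read %s: arm identity %.2f below %.2f",
                read_id,
                aln.identity,
                config.min_identity,
            )
            continue
        states = call_dyads(aln, reference, cpg_positions, config)
        records.append(
            MoleculeRecord(
                sample_id=_sample_id_from_read_id(read_id),
                umi=umi,
                dyad_states=states,
                control_c_total=ctrl_total,
                control_c_unconverted=ctrl_unconv,
            )
        )
        qc["ok"] += 1
    return dedup_umi(records), qc
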