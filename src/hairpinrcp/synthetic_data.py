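"""Synthetic hairpin-bisulfite data with controlled concordance preference.

Emulates the data-generating process behind a dyad-level methylation
study of a short amplicon: double-stranded molecules whose CpG dyads are
drawn i.i.d. from a population with single-strand methylation level ``m``
and a target Ratio of Concordance Preference; bisulfite conversion with
its two error channels (failed conversion of unmethylated C, default
rate 0.0039; inappropriate conversion of methylated C, default 0.017);
and the hairpin read layout — top arm, UMI-barcoded linker, then the
bottom strand read 5'->3' (the complement of the top arm) — so that both
strands of one molecule occupy a single read.  A companion generator
builds beta-value matrices carrying a linear age signal plus a
group-specific offset for the clock stage.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._util import revcomp

__all__ = [
    "SimSpec",
    "TrueMolecule",
    "DEFAULT_LINKER",
    "solve_dyad_distribution",
    "simulate_molecules",
    "make_reference",
    "emit_hairpin_reads",
    "simulate_beta_matrix",
    "make_synthetic_clock",
]

# Fixture linker: 10 nt arms around an 8 nt UMI slot (N run).  The arm
# cytosines are known-unmethylated conversion controls.  A real hairpin
# linker sequence would replace this via SimSpec.linker_sequence.
DEFAULT_LINKER = "GCTCAGATGT" + "N" * 8 + "ACATCTGAGC"

_UMI_ALPHABET = "AGT"  # no C: bisulfite conversion would rewrite it


@dataclass(frozen=True)
class SimSpec:
    """Full parameterisation of the synthetic generator."""

    n_individuals_per_group: int = 6
    molecules_per_individual: int = 50
    n_cpg_sites: int = 5
    m: float = 0.5
    target_rcp: float = 1.0
    fail_rate: float = 0.0039
    inappropriate_rate: float = 0.017
    linker_sequence: str = DEFAULT_LINKER
    umi_length: int = 8
    slippage_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("m must lie in [0, 1]")
        for name in ("fail_rate", "inappropriate_rate", "slippage_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5)")
        if self.target_rcp < 0:
            raise ValueError("target_rcp must be nonnegative (inf allowed)")
        if self.n_cpg_sites < 1 or self.molecules_per_individual < 1:
            raise ValueError("need at least one CpG site and one molecule")
        if self.umi_length < 1:
            raise ValueError("umi_length must be positive")
        n_run = self.linker_sequence.count("N")
        if n_run != self.umi_length or "N" * self.umi_length not in self.linker_sequence:
            raise ValueError(
                "linker_sequence must contain one contiguous run of "
                f"{self.umi_length} N's marking the UMI slot"
            )


@dataclass(frozen=True)
class TrueMolecule:
    """Ground-truth double-stranded molecule.

    dyad_states uses M / U / Ht / Hb, distinguishing which strand of a
    hemimethylated dyad carries the methyl group (needed to emit reads;
    both collapse to H downstream).
    """

    individual_id: str
    dyad_states: tuple[str, ...]
    umi: str

    def collapsed_states(self) -> tuple[str, ...]:
        return tuple("H" if s in ("Ht", "Hb") else s for s in self.dyad_states)


def solve_dyad_distribution(m: float, target_rcp: float) -> tuple[float, float, float]:
    """Dyad-state probabilities (pM, pU, pH) with level m and given RCP.

    Solves the two linear constraints pM + pU + pH = 1 and
    pM + pH/2 = m together with pM*pU = target_rcp * (pH/2)**2, which is
    quadratic in pH.  target_rcp = 1 gives the independent-placement
    null pH = 2m(1-m); target_rcp = inf gives pH = 0; target_rcp = 0
    gives the maximal feasible hemimethylation pH = 2*min(m, 1-m).
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must lie in [0, 1]")
    if target_rcp < 0:
        raise ValueError("target_rcp must be nonnegative")
    if m in (0.0, 1.0):
        if math.isinf(target_rcp) or target_rcp == 0:
            # degenerate: all-U or all-M, no hemimethylation possible
            return (m, 1.0 - m, 0.0)
        raise ValueError(
            f"m={m} admits no hemimethylated dyads; finite nonzero RCP is "
            "infeasible (feasible targets: 0 <= RCP <= inf requires 0 < m < 1)"
        )
    if math.isinf(target_rcp):
        return (m, 1.0 - m, 0.0)
    if target_rcp == 1.0:
        h = m * (1.0 - m)
    else:
        # (1-r) h^2 - h + m(1-m) = 0 with h = pH/2
        r = target_rcp
        disc = 1.0 - 4.0 * (1.0 - r) * m * (1.0 - m)
        if disc < 0:  # cannot occur for r >= 0, m in (0,1); guard anyway
            raise ValueError(
                f"(m={m}, target_rcp={r}) infeasible; any RCP in [0, inf] is "
                "feasible only for 0 < m < 1"
            )
        if r > 1.0:
            h = (math.sqrt(1.0 + 4.0 * (r - 1.0) * m * (1.0 - m)) - 1.0) / (2.0 * (r - 1.0))
        else:
            h = (1.0 - math.sqrt(disc)) / (2.0 * (1.0 - r))
    pH = 2.0 * h
    pM = m - h
    pU = 1.0 - m - h
    # numerical tidy-up at the feasibility boundary
    pM, pU, pH = (max(0.0, p) for p in (pM, pU, pH))
    s = pM + pU + pH
    return (pM / s, pU / s, pH / s)


def _unique_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if n > len(_UMI_ALPHABET) ** length:
        raise ValueError("UMI space too small for requested molecule count")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        umi = "".join(rng.choice(list(_UMI_ALPHABET), size=length))
        if umi not in seen:
            seen.add(umi)
            out.append(umi)
    return out


def simulate_molecules(
    spec: SimSpec, individual_prefix: str = "ind"
) -> dict[str, list[TrueMolecule]]:
    """Draw the ground-truth molecule population for one group.

    Each dyad is drawn i.i.d. from solve_dyad_distribution(spec.m,
    spec.target_rcp); hemimethylation lands on the top or bottom strand
    with probability 1/2 each.  UMIs are unique per molecule within an
    individual.  Deterministic for a fixed spec (including seed).
    """
    pM, pU, pH = solve_dyad_distribution(spec.m, spec.target_rcp)
    rng = np.random.default_rng(spec.seed)
    out: dict[str, list[TrueMolecule]] = {}
    states = np.array(["M", "U", "Ht", "Hb"])
    probs = np.array([pM, pU, pH / 2.0, pH / 2.0])
    probs = probs / probs.sum()
    for i in range(spec.n_individuals_per_group):
        ind_id = f"{individual_prefix}{i + 1:02d}"
        umis = _unique_umis(spec.molecules_per_individual, spec.umi_length, rng)
        mols = []
        for j in range(spec.molecules_per_individual):
            dyads = tuple(rng.choice(states, size=spec.n_cpg_sites, p=probs))
            mols.append(TrueMolecule(ind_id, dyads, umis[j]))
        out[ind_id] = mols
    return out


def make_reference(
    n_cpg: int = 5, length: int = 100, seed: int = 7
) -> tuple[str, tuple[int, ...]]:
    """Synthetic amplicon reference with exactly n_cpg CpG dinucleotides.

    Returns the top-strand sequence and the 0-based positions of the
    CpG cytosines, evenly spaced away from the ends.  Accidental CG
    dinucleotides elsewhere are rewritten so the stated positions are
    the only dyads.
    """
    if length < 10 * n_cpg:
        raise ValueError("reference too short for requested CpG count")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    margin = 5
    if n_cpg == 1:
        positions = [length // 2]
    else:
        step = (length - 2 * margin - 2) / (n_cpg - 1)
        positions = [margin + round(i * step) for i in range(n_cpg)]
    for p in positions:
        seq[p], seq[p + 1] = "C", "G"
    cpg = set(positions)
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in cpg:
            # break the stray dyad without touching a planted one
            if i + 1 not in cpg and i + 1 not in {p + 1 for p in cpg}:
                seq[i + 1] = "A"
            else:
                seq[i] = "T"
    return "".join(seq), tuple(positions)


def _bisulfite(
    seq: str,
    methylated: set[int],
    fail_rate: float,
    inappropriate_rate: float,
    rng: np.random.Generator,
) -> str:
    out = []
    for i, b in enumerate(seq):
        if b == "C":
            if i in methylated:
                out.append("T" if rng.random() < inappropriate_rate else "C")
            else:
                out.append("C" if rng.random() < fail_rate else "T")
        else:
            out.append(b)
    return "".join(out)


def _apply_slippage(seq: str, rng: np.random.Generator) -> str:
    """One 1-2 nt insertion or deletion at a uniform position."""
    size = int(rng.integers(1, 3))
    pos = int(rng.integers(0, len(seq)))
    if rng.random() < 0.5:
        ins = "".join(rng.choice(list("ACGT"), size=size))
        return seq[:pos] + ins + seq[pos:]
    return seq[:pos] + seq[pos + size :]


def emit_hairpin_reads(
    molecules: dict[str, list[TrueMolecule]],
    spec: SimSpec,
    reference: str,
    cpg_positions: tuple[int, ...],
) -> list[tuple[str, str]]:
    """Render molecules as hairpin-bisulfite reads.

    Read layout: bisulfite-converted top strand (5'->3'), then the
    linker with its UMI filled in (linker cytosines are unmethylated
    conversion controls), then the bisulfite-converted bottom strand
    read 5'->3' — i.e. the complement of the top arm, so reversing the
    right arm aligns it base-for-base under the top arm.

    Returns (read_id, sequence) pairs; read_id is "<individual>|<n>".
    Deterministic given spec.seed.
    """
    if len(cpg_positions) != spec.n_cpg_sites:
        raise ValueError(
            f"reference has {len(cpg_positions)} CpG sites but spec expects "
            f"{spec.n_cpg_sites}"
        )
    for p in cpg_positions:
        if reference[p : p + 2] != "CG":
            raise ValueError(f"position {p} of reference is not a CpG")
    L = len(reference)
    bottom = revcomp(reference)  # bottom strand 5'->3'
    rng = np.random.default_rng([int(spec.seed) % (2**31), 0x5EAD])
    reads: list[tuple[str, str]] = []
    for ind_id in sorted(molecules):
        for j, mol in enumerate(molecules[ind_id]):
            top_meth = {
                p for p, s in zip(cpg_positions, mol.dyad_states) if s in ("M", "Ht")
            }
            # bottom-strand CpG C sits opposite the top G, at bottom index L-2-p
            bot_meth = {
                L - 2 - p
                for p, s in zip(cpg_positions, mol.dyad_states)
                if s in ("M", "Hb")
            }
            top_arm = _bisulfite(
                reference, top_meth, spec.fail_rate, spec.inappropriate_rate, rng
            )
            bottom_arm = _bisulfite(
                bottom, bot_meth, spec.fail_rate, spec.inappropriate_rate, rng
            )
            linker = spec.linker_sequence.replace("N" * spec.umi_length, mol.umi)
            linker = _bisulfite(
                linker, set(), spec.fail_rate, spec.inappropriate_rate, rng
            )
            read = top_arm + linker + bottom_arm
            if spec.slippage_rate > 0 and rng.random() < spec.slippage_rate:
                read = _apply_slippage(read, rng)
            reads.append((f"{ind_id}|{j}", read))
    return reads


def make_synthetic_clock(n_probes: int = 10, name: str = "synthetic-clock"):
    """A small linear clock for simulations (synthetic, not a published set).

    Alternating +/-1 coefficients sum to zero for even n_probes, so the
    linear score is a pure contrast of probe betas and the minimum-norm
    beta construction in simulate_beta_matrix stays inside [0, 1] for
    ages 0-100.
    """
    from .clock_age import ClockModel

    coefs = {
        f"cgSYN{i + 1:04d}": (1.0 if i % 2 == 0 else -1.0) for i in range(n_probes)
    }
    return ClockModel(
        name=name,
        coefficients=coefs,
        intercept=0.0,
        transform="horvath_piecewise",
        adult_age=20.0,
    )


def simulate_beta_matrix(
    n_per_group: tuple[int, int],
    ages,
    clock,
    group_offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    group_names: tuple[str, str] = ("groupA", "groupB"),
    base_beta: float = 0.5,
):
    """Beta matrix + sample sheet with a recoverable age signal.

    Constructs probe betas so that applying `clock` returns
    age + offset + noise exactly: the target epigenetic age for each
    sample is transformed to the clock's linear scale and the required
    shift is spread over the clock probes along the coefficient vector
    (minimum-norm solution around `base_beta`).  The offset is added to
    the second group only.

    ages: sequence of chronological ages of length sum(n_per_group), or
    None to draw uniformly from 18-35 years.

    Raises ValueError if the construction would leave [0, 1].
    """
    import pandas as pd

    from .clock_age import transform_age

    n_a, n_b = n_per_group
    n = n_a + n_b
    rng = np.random.default_rng(seed)
    if ages is None:
        ages = rng.uniform(18.0, 35.0, size=n)
    ages = np.asarray(ages, dtype=float)
    if ages.shape != (n,):
        raise ValueError(f"need {n} ages, got shape {ages.shape}")
    if (ages < 0).any():
        raise ValueError("ages must be nonnegative")

    labels = np.array([group_names[0]] * n_a + [group_names[1]] * n_b)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    target = ages + np.where(labels == group_names[1], group_offset, 0.0) + noise
    if (target < 0).any():
        raise ValueError("offset/noise drove a target epigenetic age below 0")

    w = np.array([clock.coefficients[p] for p in clock.coefficient_order()])
    x = transform_age(target, clock.adult_age) if clock.transform == "horvath_piecewise" else target
    d = x - clock.intercept - w.sum() * base_beta
    betas = base_beta + np.outer(w / np.dot(w, w), d)
    if betas.min() < 0 or betas.max() > 1:
        raise ValueError(
            "constructed betas leave [0, 1]; rescale clock coefficients or "
            "reduce the offset/noise"
        )
    sample_ids = [f"s{i + 1:02d}" for i in range(n)]
    beta_df = pd.DataFrame(betas, index=clock.coefficient_order(), columns=sample_ids)
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "group": labels, "age": ages}
    )
    return beta_df, sheet
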