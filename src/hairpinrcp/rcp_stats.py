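"""Ratio of Concordance Preference (RCP) statistics.

A CpG dyad is the pair of complementary CpG sites at one position on the
two strands of a double-stranded DNA molecule.  Each dyad is fully
methylated (M), fully unmethylated (U), or hemimethylated (H).  With
fractions fM, fU, fH (fM + fU + fH = 1) and single-strand methylation
level m = fM + fH/2, the Ratio of Concordance Preference is

    RCP = fM * fU / (fH / 2)**2  =  fU * (fU + 2m - 1) / (1 - fU - m)**2

using the identities fM = fU + 2m - 1 and fH/2 = 1 - fU - m.  Under a
null model in which methyl groups are placed independently on the two
strands at level m, fM = m**2, fU = (1-m)**2, fH = 2m(1-m) and RCP = 1.
RCP = 0 at complete discordance (only hemimethylated dyads) and
RCP -> infinity at complete concordance (no hemimethylated dyads).

This module also corrects observed dyad counts for the two bisulfite
conversion error channels, and infers group differences in RCP through
a hierarchical (individuals, then molecules) bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DyadCounts",
    "ErrorRates",
    "RCPComparison",
    "compute_rcp",
    "forward_error_matrix",
    "correct_counts",
    "bootstrap_pvalues",
    "hierarchical_bootstrap",
]

logger = logging.getLogger(__name__)

# dyad-state index order used throughout: 0 = M, 1 = U, 2 = H
STATE_ORDER = ("M", "U", "H")


@dataclass(frozen=True)
class DyadCounts:
    """Counts (real-valued; bootstrap rescaling produces fractional counts)."""

    M: float
    U: float
    H: float

    def __post_init__(self) -> None:
        if self.M < 0 or self.U < 0 or self.H < 0:
            raise ValueError("dyad counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.M + self.U + self.H

    @property
    def fractions(self) -> tuple[float, float, float]:
        t = self.total
        if t <= 0:
            raise ValueError("cannot form fractions from all-zero dyad counts")
        return (self.M / t, self.U / t, self.H / t)

    @property
    def methylation_level(self) -> float:
        fM, _, fH = self.fractions
        return fM + fH / 2.0

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.U, self.H], dtype=float)


@dataclass(frozen=True)
class ErrorRates:
    """Bisulfite conversion error rates.

    fail_rate: probability an unmethylated C escapes conversion and is
        read as methylated (default 0.0039, the empirically measured
        hairpin-control rate).
    inappropriate_rate: probability a methylated C is converted anyway
        and read as unmethylated (default 0.017).
    """

    fail_rate: float = 0.0039
    inappropriate_rate: float = 0.017

    def __post_init__(self) -> None:
        for name in ("fail_rate", "inappropriate_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5), got {v}")


def _rcp_from_fractions(fM, fU, fH, variant: str = "ratio"):
    """Vectorised RCP on fraction arrays; returns inf where fH == 0."""
    fM = np.asarray(fM, dtype=float)
    fU = np.asarray(fU, dtype=float)
    fH = np.asarray(fH, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(fH > 0, fM * fU / np.square(fH / 2.0), np.inf)
    if variant == "sqrt":
        r = np.sqrt(r)
    elif variant != "ratio":
        raise ValueError(f"unknown RCP variant {variant!r}")
    return r


def compute_rcp(counts: DyadCounts, variant: str = "ratio") -> float:
    """RCP of one set of dyad counts.

    Conventions at the boundary: fH = 0 yields +inf (no discordant
    evidence, including the degenerate all-M / all-U case); fH > 0 with
    fM = 0 or fU = 0 yields 0.  All-zero counts are an error.

    variant="sqrt" returns sqrt(fM*fU)/(fH/2), a monotone transform with
    the same anchor values (0, 1, inf); group-difference signs are
    invariant to the choice.
    """
    fM, fU, fH = counts.fractions
    return float(_rcp_from_fractions(fM, fU, fH, variant=variant))


def forward_error_matrix(rates: ErrorRates) -> np.ndarray:
    """3x3 column-stochastic matrix T with observed = T @ true.

    Per-strand channel: a truly methylated strand reads unmethylated
    with probability q (inappropriate_rate); a truly unmethylated strand
    reads methylated with probability f (fail_rate); the two strands err
    independently.  Rows/columns ordered (M, U, H).
    """
    f = rates.fail_rate
    q = rates.inappropriate_rate
    return np.array(
        [
            # true M           true U            true H
            [(1 - q) ** 2,     f**2,             f * (1 - q)],
            [q**2,             (1 - f) ** 2,     q * (1 - f)],
            [2 * q * (1 - q),  2 * f * (1 - f),  (1 - q) * (1 - f) + q * f],
        ],
        dtype=float,
    )


def correct_counts(observed: DyadCounts, rates: ErrorRates) -> DyadCounts:
    """Invert the conversion-error channel on observed dyad counts.

    Solves T @ true_fracs = observed_fracs, clips negative solutions to
    zero, renormalises, and rescales to the observed total.
    """
    T = forward_error_matrix(rates)
    if abs(np.linalg.det(T)) < 1e-12:
        raise ValueError("error channel is singular; rates are too extreme")
    obs = np.asarray(observed.fractions, dtype=float)
    true = np.linalg.solve(T, obs)
    true = np.clip(true, 0.0, None)
    s = true.sum()
    if s <= 0:
        raise ValueError("correction produced all-zero fractions")
    true = true / s * observed.total
    return DyadCounts(M=float(true[0]), U=float(true[1]), H=float(true[2]))


def _correct_fraction_rows(fracs: np.ndarray, rates: ErrorRates) -> np.ndarray:
    """Row-wise channel inversion for (n, 3) observed fraction arrays."""
    T = forward_error_matrix(rates)
    true = fracs @ np.linalg.inv(T).T
    true = np.clip(true, 0.0, None)
    s = true.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, true / s, np.nan)
    return out


def bootstrap_pvalues(diff_samples) -> tuple[float, float]:
    """One- and two-tailed p-values from bootstrap difference samples.

    One-tailed: the proportion of difference samples at or left of 0
    (zeros count as left — conservative).  Two-tailed: twice the smaller
    of the proportions on either side of 0, capped at 1.
    """
    d = np.asarray(diff_samples, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference sample list")
    left = float(np.mean(d <= 0))
    right = float(np.mean(d >= 0))
    return left, min(1.0, 2.0 * min(left, right))


@dataclass
class RCPComparison:
    """Hierarchical-bootstrap comparison of RCP between two groups.

    diff_samples holds rcp(first group) - rcp(second group) per replicate;
    the one-tailed p-value is the fraction of differences <= 0, i.e. the
    evidence against "first group has higher RCP".
    """

    group_names: tuple[str, str]
    group_rcp_samples: dict[str, np.ndarray]
    diff_samples: np.ndarray
    rcp_point: dict[str, float]
    p_one_tailed: float
    p_two_tailed: float
    B: int
    seed: int
    rates: ErrorRates
    n_redrawn: int = 0
    variant: str = "ratio"

    def summary(self) -> dict:
        def _quant(x):
            finite = x[np.isfinite(x)]
            if finite.size == 0:
                return {}
            qs = np.quantile(finite, [0.025, 0.25, 0.5, 0.75, 0.975])
            return dict(zip(["q2.5", "q25", "q50", "q75", "q97.5"], map(float, qs)))

        return {
            "groups": list(self.group_names),
            "rcp_point": {k: float(v) for k, v in self.rcp_point.items()},
            "rcp_bootstrap_quantiles": {
                g: _quant(self.group_rcp_samples[g]) for g in self.group_names
            },
            "p_one_tailed": self.p_one_tailed,
            "p_two_tailed": self.p_two_tailed,
            "B": self.B,
            "seed": self.seed,
            "fail_rate": self.rates.fail_rate,
            "inappropriate_rate": self.rates.inappropriate_rate,
            "n_redrawn": self.n_redrawn,
            "variant": self.variant,
        }


def _as_count_arrays(individuals) -> list[np.ndarray]:
    out = []
    for ind in individuals:
        arr = np.asarray(ind, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("each individual needs an (n_molecules, 3) count array")
        if arr.shape[0] < 1:
            raise ValueError("each individual needs at least one molecule")
        out.append(arr)
    return out


def _draw_group_counts(
    ind_counts: list[np.ndarray],
    n_rep: int,
    common_total: float,
    rng: np.random.Generator,
    pseudocount: float,
) -> np.ndarray:
    """One group's bootstrap: (n_rep, 3) summed, equal-weight dyad counts.

    Individuals are resampled with replacement; within each sampled
    individual, molecules are resampled with replacement (multinomial
    over its molecules); each sampled individual's counts are rescaled
    to `common_total` dyads before summing (fractional counts kept).
    """
    n_ind = len(ind_counts)
    choice = rng.integers(0, n_ind, size=(n_rep, n_ind))
    slot_counts = np.zeros((n_rep, n_ind, 3), dtype=float)
    for i, C in enumerate(ind_counts):
        mask = choice == i
        k = int(mask.sum())
        if k == 0:
            continue
        n_mol = C.shape[0]
        mult = rng.multinomial(n_mol, np.full(n_mol, 1.0 / n_mol), size=k)
        slot_counts[mask] = mult.astype(float) @ C
    totals = slot_counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, slot_counts * (common_total / totals), 0.0)
    return scaled.sum(axis=1) + pseudocount


def _equal_weight_counts(ind_counts: list[np.ndarray], common_total: float) -> DyadCounts:
    rows = []
    for C in ind_counts:
        s = C.sum(axis=0)
        t = s.sum()
        if t > 0:
            rows.append(s / t * common_total)
    agg = np.sum(rows, axis=0)
    return DyadCounts(*map(float, agg))


def hierarchical_bootstrap(
    groups: dict[str, list],
    B: int = 20_000,
    rates: ErrorRates = ErrorRates(),
    seed: int = 0,
    variant: str = "ratio",
    pseudocount: float = 0.0,
    max_passes: int = 200,
) -> RCPComparison:
    """Two-group hierarchical bootstrap of the RCP difference.

    Parameters
    ----------
    groups
        Mapping of exactly two group names to lists of per-individual
        molecule count arrays, each of shape (n_molecules, 3) in state
        order (M, U, H).  A molecule's row is its dyad-state tally.
    B
        Number of bootstrap replicates (default 20,000).
    pseudocount
        Optional Haldane-style count added to each of M, U, H of a
        replicate's summed group counts (default 0: no pseudocount).

    Replicates in which either group has no informative dyads, or in
    which both groups are infinitely concordant (an undefined inf - inf
    difference), are redrawn; the number redrawn is reported.
    """
    if len(groups) != 2:
        raise ValueError("hierarchical_bootstrap compares exactly two groups")
    (name_a, inds_a), (name_b, inds_b) = groups.items()
    inds_a = _as_count_arrays(inds_a)
    inds_b = _as_count_arrays(inds_b)
    if B < 1:
        raise ValueError("B must be positive")

    # common per-individual dyad total = mean observed total in the group
    tot_a = float(np.mean([C.sum() for C in inds_a]))
    tot_b = float(np.mean([C.sum() for C in inds_b]))
    if tot_a <= 0 or tot_b <= 0:
        raise ValueError("a group has no informative dyads")

    rng = np.random.default_rng(seed)
    kept_a: list[np.ndarray] = []
    kept_b: list[np.ndarray] = []
    need, n_redrawn, passes = B, 0, 0
    while need > 0:
        passes += 1
        if passes > max_passes:
            raise RuntimeError(
                "bootstrap failed to produce valid replicates "
                f"(still missing {need} after {max_passes} passes); "
                "consider pseudocount > 0"
            )
        counts_a = _draw_group_counts(inds_a, need, tot_a, rng, pseudocount)
        counts_b = _draw_group_counts(inds_b, need, tot_b, rng, pseudocount)
        sum_a = counts_a.sum(axis=1, keepdims=True)
        sum_b = counts_b.sum(axis=1, keepdims=True)
        ok = (sum_a[:, 0] > 0) & (sum_b[:, 0] > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fr_a = _correct_fraction_rows(np.where(sum_a > 0, counts_a / sum_a, 0), rates)
            fr_b = _correct_fraction_rows(np.where(sum_b > 0, counts_b / sum_b, 0), rates)
        rcp_a = _rcp_from_fractions(fr_a[:, 0], fr_a[:, 1], fr_a[:, 2], variant)
        rcp_b = _rcp_from_fractions(fr_b[:, 0], fr_b[:, 1], fr_b[:, 2], variant)
        diff = rcp_a - rcp_b
        ok &= ~np.isnan(diff)  # nan marks inf - inf or failed correction
        n_bad = int(need - ok.sum())
        if n_bad:
            n_redrawn += n_bad
            logger.info("redrawing %d invalid bootstrap replicates", n_bad)
        kept_a.append(rcp_a[ok])
        kept_b.append(rcp_b[ok])
        need -= int(ok.sum())

    samples_a = np.concatenate(kept_a)[:B]
    samples_b = np.concatenate(kept_b)[:B]
    diffs = samples_a - samples_b
    p1, p2 = bootstrap_pvalues(diffs)

    point = {
        name_a: compute_rcp(
            correct_counts(_equal_weight_counts(inds_a, tot_a), rates), variant
        ),
        name_b: compute_rcp(
            correct_counts(_equal_weight_counts(inds_b, tot_b), rates), variant
        ),
    }
    return RCPComparison(
        group_names=(name_a, name_b),
        group_rcp_samples={name_a: samples_a, name_b: samples_b},
        diff_samples=diffs,
        rcp_point=point,
        p_one_tailed=p1,
        p_two_tailed=p2,
        B=B,
        seed=seed,
        rates=rates,
        n_redrawn=n_redrawn,
        variant=variant,
    )


def molecule_count_arrays(records, sample_groups: dict[str, str]) -> dict[str, list]:
    """Group MoleculeRecord-like objects into bootstrap input arrays.

    records need `sample_id` and `dyad_states` attributes; ambiguous
    states ('.') are not counted.  sample_groups maps sample_id -> group
    label.  Returns {group: [per-individual (n_molecules, 3) array]}.
    """
    per_sample: dict[str, list[list[float]]] = {}
    for rec in records:
        row = [
            sum(1.0 for s in rec.dyad_states if s == st) for st in STATE_ORDER
        ]
        per_sample.setdefault(rec.sample_id, []).append(row)
    out: dict[str, list] = {}
    for sample_id, rows in sorted(per_sample.items()):
        group = sample_groups.get(sample_id)
        if group is None:
            raise KeyError(f"sample {sample_id!r} missing from sample sheet")
        arr = np.asarray(rows, dtype=float)
        if arr.sum() == 0:
            logger.warning("sample %s has no informative dyads; excluded", sample_id)
            continue
        out.setdefault(group, []).append(arr)
    return out
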