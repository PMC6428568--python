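"""Courtship-memory statistics: CI, SI and permutation tests.

The courtship index (CI) of a male is the percentage of a 10-min test during
which he courts the female.  Memory after courtship conditioning is read out
as a suppression index

    SI = 100 * (1 - CI_trained / CI_naive)

where ``CI_trained`` and ``CI_naive`` are group centers (mean by default,
median by option).  Significance is assessed with a label-permutation null:
all CIs are pooled and randomly re-assorted into simulated naive and trained
groups of the original sizes, an SI is computed for each of (by default)
100,000 permuted data sets, and the p-value is the fraction of the null at
least as extreme as the observed statistic.  Two null hypotheses are
supported: H0: SI = 0 (one group pair) and H0: SI = SI_c (an experimental
versus a control genotype, statistic delta-SI).

When the number of distinct label assignments is small the test enumerates
all of them and reports the exact proportion instead of sampling.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from flysleepmem.exceptions import UndefinedSIError, ValidationError

#: Enumerate the null exactly when the number of distinct label assignments
#: is at most this; otherwise sample with replacement.
EXHAUSTIVE_CAP = 200_000

#: Default number of sampled permutations.
DEFAULT_N_PERMUTATIONS = 100_000

#: Fraction of permutations with an undefined SI above which the test aborts.
MAX_EXCLUDED_FRACTION = 0.01

Center = Literal["mean", "median"]
Tail = Literal["greater", "two_sided"]

CONDITIONS = ("trained", "naive")


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class BoutRecord:
    """Courting intervals of one male during one videotaped test.

    ``courting_intervals`` are half-open ``(start_s, end_s)`` pairs, sorted,
    non-overlapping, within ``[0, test_duration_s)``.
    """

    fly_id: str
    test_duration_s: float
    courting_intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.test_duration_s <= 0:
            raise ValidationError("test_duration_s must be positive")
        prev_end = 0.0
        for start, end in self.courting_intervals:
            if start < 0 or end > self.test_duration_s or start >= end:
                raise ValidationError(
                    f"interval ({start}, {end}) outside [0, {self.test_duration_s})"
                )
            if start < prev_end:
                raise ValidationError("courting intervals overlap or are unsorted")
            prev_end = end


@dataclass
class CourtshipTable:
    """Per-fly courtship indices with genotype and condition labels.

    Backed by a DataFrame with columns ``fly_id, genotype, condition, ci``;
    ``condition`` is ``trained`` or ``naive`` and ``ci`` is a percentage in
    [0, 100].
    """

    df: pd.DataFrame

    REQUIRED_COLUMNS = ("fly_id", "genotype", "condition", "ci")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"courtship table missing columns {missing}")
        df = self.df
        if df["fly_id"].duplicated().any():
            dupes = df.loc[df["fly_id"].duplicated(), "fly_id"].tolist()
            raise ValidationError(f"duplicate fly_id values: {dupes}")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels {sorted(bad)}")
        ci = df["ci"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ci)) or ci.min() < 0 or ci.max() > 100:
            raise ValidationError("ci values must be finite and within [0, 100]")

    def cis(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}")
        return self.df.loc[self.df["condition"] == condition, "ci"].to_numpy(float)

    @property
    def n_trained(self) -> int:
        return int((self.df["condition"] == "trained").sum())

    @property
    def n_naive(self) -> int:
        return int((self.df["condition"] == "naive").sum())

    @classmethod
    def from_arrays(
        cls,
        trained_cis: Sequence[float],
        naive_cis: Sequence[float],
        genotype: str = "wt",
        fly_prefix: str = "fly",
    ) -> "CourtshipTable":
        records = []
        for i, ci in enumerate(trained_cis):
            records.append((f"{fly_prefix}_t{i}", genotype, "trained", float(ci)))
        for i, ci in enumerate(naive_cis):
            records.append((f"{fly_prefix}_n{i}", genotype, "naive", float(ci)))
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED_COLUMNS)))

    @classmethod
    def read_csv(cls, path) -> "CourtshipTable":
        return cls(pd.read_csv(path, dtype={"fly_id": str, "genotype": str}))

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False, columns=list(self.REQUIRED_COLUMNS))


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test, including a summary of the null."""

    observed_statistic: float
    n_permutations: int
    p_value: float
    tail: Tail
    null_summary: dict
    seed: int | str
    center: Center
    statistic: str  # "SI" or "delta_SI"
    n_excluded: int = 0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed_statistic": self.observed_statistic,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "tail": self.tail,
            "center": self.center,
            "seed": self.seed,
            "null_summary": self.null_summary,
            "n_excluded": self.n_excluded,
            "degenerate": self.degenerate,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"schema_version": 1, **self.to_dict()}, fh, indent=2)


# ---------------------------------------------------------------------------
# Indices


def courtship_index(bouts: BoutRecord) -> float:
    """CI = 100 * (total courting time) / (test duration), a percentage."""
    total = sum(end - start for start, end in bouts.courting_intervals)
    return 100.0 * total / bouts.test_duration_s


def _center_fn(center: Center):
    if center == "mean":
        return np.mean
    if center == "median":
        return np.median
    raise ValidationError(f"center must be 'mean' or 'median', got {center!r}")


def suppression_index(
    trained_cis: Sequence[float],
    naive_cis: Sequence[float],
    center: Center = "mean",
) -> float:
    """SI = 100 * (1 - center(trained CIs) / center(naive CIs)).

    SI <= 100 always; negative values mean the trained group courted *more*.
    Raises :class:`UndefinedSIError` when the naive center is zero.
    """
    trained = np.asarray(trained_cis, dtype=float)
    naive = np.asarray(naive_cis, dtype=float)
    if trained.size == 0 or naive.size == 0:
        raise ValidationError("both CI lists must be non-empty")
    fn = _center_fn(center)
    naive_c = float(fn(naive))
    if naive_c == 0:
        raise UndefinedSIError("naive-group center is 0; SI undefined")
    return 100.0 * (1.0 - float(fn(trained)) / naive_c)


# ---------------------------------------------------------------------------
# Permutation internals


def _null_summary(null: np.ndarray) -> dict:
    if null.size == 0:
        return {"mean": None, "sd": None, "quantiles": {}}
    qs = np.quantile(null, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "mean": float(null.mean()),
        "sd": float(null.std(ddof=0)),
        "quantiles": {
            "q025": float(qs[0]),
            "q25": float(qs[1]),
            "q50": float(qs[2]),
            "q75": float(qs[3]),
            "q975": float(qs[4]),
        },
    }


def _tail_count(null: np.ndarray, observed: float, tail: Tail) -> int:
    if tail == "greater":
        return int(np.count_nonzero(null >= observed))
    if tail == "two_sided":
        return int(np.count_nonzero(np.abs(null) >= abs(observed)))
    raise ValidationError(f"tail must be 'greater' or 'two_sided', got {tail!r}")


def _si_from_matrix(
    trained: np.ndarray, naive: np.ndarray, center: Center
) -> tuple[np.ndarray, int]:
    """Row-wise SI with the undefined-SI guard.

    Rows whose naive center is zero have no defined SI; they are dropped and
    counted.  Returns (si values of defined rows, number excluded).
    """
    fn = _center_fn(center)
    t_c = fn(trained, axis=1)
    n_c = fn(naive, axis=1)
    ok = n_c != 0
    n_excluded = int(np.count_nonzero(~ok))
    si = 100.0 * (1.0 - t_c[ok] / n_c[ok])
    return si, n_excluded


def _check_excluded(n_excluded: int, n_total: int) -> None:
    if n_total and n_excluded / n_total > MAX_EXCLUDED_FRACTION:
        raise UndefinedSIError(
            f"{n_excluded}/{n_total} permutations had an undefined SI "
            f"(naive center 0); more than {MAX_EXCLUDED_FRACTION:.0%} excluded"
        )


def _sampled_group_matrices(
    pool: np.ndarray, n_first: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly re-assort ``pool`` into two groups of fixed sizes, n_perm times."""
    mat = np.tile(pool, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    return mat[:, :n_first], mat[:, n_first:]


def _exhaustive_split_indices(n: int, n_first: int) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays for every way to split range(n) into groups of n_first / rest."""
    first = np.array(
        list(itertools.combinations(range(n), n_first)), dtype=np.intp
    ).reshape(-1, n_first)
    all_idx = np.arange(n, dtype=np.intp)
    rest = np.array(
        [np.setdiff1d(all_idx, row, assume_unique=True) for row in first],
        dtype=np.intp,
    ).reshape(first.shape[0], n - n_first)
    return first, rest


# ---------------------------------------------------------------------------
# Tests


def permutation_test_si_zero(
    table: CourtshipTable,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    center: Center = "mean",
    tail: Tail = "greater",
    seed: int | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> PermutationResult:
    """Permutation test of H0: SI = 0 for one trained/naive table.

    All CIs are pooled and re-assorted into simulated trained and naive
    groups of the original sizes; an SI is computed for each permuted data
    set.  When the number of distinct assignments C(n, n_trained) is at most
    ``exhaustive_cap`` every assignment is enumerated and the exact
    proportion is reported (``seed`` is then recorded as ``"exhaustive"``);
    otherwise ``n_permutations`` random assignments are drawn and the
    add-one-corrected p-value ``(1 + #extreme) / (1 + n_permutations)`` is
    reported.

    A fully degenerate pool (all CIs identical) yields SI = 0, p = 1 with
    ``degenerate=True`` rather than an error.
    """
    trained = table.cis("trained")
    naive = table.cis("naive")
    if trained.size == 0 or naive.size == 0:
        raise ValidationError("table needs at least one fly per condition")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")

    pool = np.concatenate([trained, naive])
    n_t = trained.size

    if np.ptp(pool) == 0:
        # No label assignment can change anything; SI is 0 for every split
        # (or undefined if the shared value is 0).
        observed = 0.0
        return PermutationResult(
            observed_statistic=observed,
            n_permutations=0,
            p_value=1.0,
            tail=tail,
            null_summary=_null_summary(np.zeros(1)),
            seed="degenerate",
            center=center,
            statistic="SI",
            degenerate=True,
        )

    observed = suppression_index(trained, naive, center=center)

    n_assignments = math.comb(pool.size, n_t)
    if n_assignments <= exhaustive_cap:
        first, rest = _exhaustive_split_indices(pool.size, n_t)
        null, n_excluded = _si_from_matrix(pool[first], pool[rest], center)
        _check_excluded(n_excluded, n_assignments)
        p = _tail_count(null, observed, tail) / null.size
        return PermutationResult(
            observed_statistic=observed,
            n_permutations=int(null.size),
            p_value=float(p),
            tail=tail,
            null_summary=_null_summary(null),
            seed="exhaustive",
            center=center,
            statistic="SI",
            n_excluded=n_excluded,
        )

    rng = np.random.default_rng(seed)
    trained_m, naive_m = _sampled_group_matrices(pool, n_t, n_permutations, rng)
    null, n_excluded = _si_from_matrix(trained_m, naive_m, center)
    _check_excluded(n_excluded, n_permutations)
    p = (1 + _tail_count(null, observed, tail)) / (1 + null.size)
    return PermutationResult(
        observed_statistic=observed,
        n_permutations=int(null.size),
        p_value=float(p),
        tail=tail,
        null_summary=_null_summary(null),
        seed=seed if seed is not None else "unseeded",
        center=center,
        statistic="SI",
        n_excluded=n_excluded,
    )


def permutation_test_si_equal(
    exp_table: CourtshipTable,
    ctrl_table: CourtshipTable,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    center: Center = "mean",
    tail: Tail = "two_sided",
    seed: int | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> PermutationResult:
    """Permutation test of H0: SI_exp = SI_ctrl (statistic delta-SI).

    The null is built by permuting flies between the experimental and
    control arms *within condition* — trained flies exchange only with
    trained flies, naive only with naive — preserving all four group sizes.
    Exhaustive enumeration is used when the number of distinct assignments
    C(Nt, nt_exp) * C(Nn, nn_exp) fits under ``exhaustive_cap``.
    """
    groups = {}
    for name, tab in (("exp", exp_table), ("ctrl", ctrl_table)):
        for cond in CONDITIONS:
            cis = tab.cis(cond)
            if cis.size == 0:
                raise ValidationError(f"{name} table has no {cond} flies")
            groups[(name, cond)] = cis
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")

    trained_pool = np.concatenate([groups[("exp", "trained")], groups[("ctrl", "trained")]])
    naive_pool = np.concatenate([groups[("exp", "naive")], groups[("ctrl", "naive")]])
    nt_e = groups[("exp", "trained")].size
    nn_e = groups[("exp", "naive")].size

    if np.ptp(np.concatenate([trained_pool, naive_pool])) == 0:
        return PermutationResult(
            observed_statistic=0.0,
            n_permutations=0,
            p_value=1.0,
            tail=tail,
            null_summary=_null_summary(np.zeros(1)),
            seed="degenerate",
            center=center,
            statistic="delta_SI",
            degenerate=True,
        )

    observed = suppression_index(
        groups[("exp", "trained")], groups[("exp", "naive")], center=center
    ) - suppression_index(
        groups[("ctrl", "trained")], groups[("ctrl", "naive")], center=center
    )

    fn = _center_fn(center)
    n_t_assign = math.comb(trained_pool.size, nt_e)
    n_n_assign = math.comb(naive_pool.size, nn_e)

    if n_t_assign * n_n_assign <= exhaustive_cap:
        # Trained-arm and naive-arm re-assortments are independent, so the
        # full null is the cross product of the two enumerations.
        te_idx, tc_idx = _exhaustive_split_indices(trained_pool.size, nt_e)
        ne_idx, nc_idx = _exhaustive_split_indices(naive_pool.size, nn_e)
        ct_e = fn(trained_pool[te_idx], axis=1)  # (n_t_assign,)
        ct_c = fn(trained_pool[tc_idx], axis=1)
        cn_e = fn(naive_pool[ne_idx], axis=1)  # (n_n_assign,)
        cn_c = fn(naive_pool[nc_idx], axis=1)
        ok = (cn_e != 0)[None, :] & (cn_c != 0)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 100.0 * (
                ct_c[:, None] / cn_c[None, :] - ct_e[:, None] / cn_e[None, :]
            )
        ok = np.broadcast_to(ok, delta.shape)
        null = delta[ok]
        n_excluded = int(delta.size - null.size)
        _check_excluded(n_excluded, delta.size)
        p = _tail_count(null, observed, tail) / null.size
        return PermutationResult(
            observed_statistic=float(observed),
            n_permutations=int(null.size),
            p_value=float(p),
            tail=tail,
            null_summary=_null_summary(null),
            seed="exhaustive",
            center=center,
            statistic="delta_SI",
            n_excluded=n_excluded,
        )

    rng = np.random.default_rng(seed)
    te, tc = _sampled_group_matrices(trained_pool, nt_e, n_permutations, rng)
    ne, nc = _sampled_group_matrices(naive_pool, nn_e, n_permutations, rng)
    ct_e, ct_c = fn(te, axis=1), fn(tc, axis=1)
    cn_e, cn_c = fn(ne, axis=1), fn(nc, axis=1)
    ok = (cn_e != 0) & (cn_c != 0)
    n_excluded = int(np.count_nonzero(~ok))
    _check_excluded(n_excluded, n_permutations)
    null = 100.0 * (ct_c[ok] / cn_c[ok] - ct_e[ok] / cn_e[ok])
    p = (1 + _tail_count(null, observed, tail)) / (1 + null.size)
    return PermutationResult(
        observed_statistic=float(observed),
        n_permutations=int(null.size),
        p_value=float(p),
        tail=tail,
        null_summary=_null_summary(null),
        seed=seed if seed is not None else "unseeded",
        center=center,
        statistic="delta_SI",
        n_excluded=n_excluded,
    )
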