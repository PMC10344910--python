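"""The dataset-size experiment: five-group rotation and halving schedule.

The design: the cohort is randomly split into five equal groups; each group
in turn is held out while the refiner trains on the other four, so every
eye receives exactly one evaluated prediction error (refined prediction
minus achieved MRSE).  The cohort is then halved repeatedly — down to 1/64
of the original size — and the rotation repeated at each size, exposing how
training-set size drives the spread of prediction errors.  Subgroup views
slice the full-size errors by axial length class and by A-constant bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics, refine
from .exceptions import InvalidConfigError, InvalidInputError
from .metrics import ErrorSummary
from .refine import RefinerConfig

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "AblationPlan",
    "AblationResult",
    "halving_schedule",
    "partition_five",
    "run_cv",
    "run_ablation",
    "subgroup_axl",
    "subgroup_aconstant",
]

N_GROUPS = 5


@dataclass
class FoldAssignment:
    labels: np.ndarray  # group index 0..4 per record position
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=N_GROUPS)
        if counts.max() - counts.min() > 1:
            raise InvalidConfigError("group sizes must differ by at most 1")


@dataclass
class AblationPlan:
    """The halving schedule and the subsampling mode."""

    sizes: list
    nested: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        s = list(self.sizes)
        if any(b >= a for a, b in zip(s, s[1:])):
            raise InvalidConfigError("sizes must be strictly decreasing")

    @classmethod
    def from_cohort_size(
        cls, full_n: int, stop_fraction: float = 1.0 / 64.0,
        nested: bool = True, seed: int = 0,
    ) -> "AblationPlan":
        return cls(halving_schedule(full_n, stop_fraction), nested, seed)


@dataclass
class AblationResult:
    """Per-size evaluation errors and summaries, with provenance."""

    sizes: list
    errors: dict          # size -> DataFrame [eye_id, error_d]
    summaries: dict       # size -> ErrorSummary
    train_sizes: dict     # size -> per-fold training size
    provenance: dict = field(default_factory=dict)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for size in self.sizes:
            s = self.summaries[size]
            rows.append(
                {
                    "dataset_size": size,
                    "training_size": self.train_sizes[size],
                    **s.as_dict(),
                }
            )
        return pd.DataFrame(rows)


def halving_schedule(full_n: int, stop_fraction: float = 1.0 / 64.0) -> list:
    """[full_n, full_n/2, ...] down to full_n * stop_fraction.

    Sizes are floored (with a warning) when the halving is not exact; the
    smallest dataset must still be able to host five groups.
    """
    if not 0 < stop_fraction <= 1:
        raise InvalidConfigError("stop_fraction must be in (0, 1]")
    if full_n * stop_fraction < N_GROUPS:
        raise InvalidConfigError(
            f"smallest dataset ({full_n * stop_fraction:.0f}) could not host "
            f"{N_GROUPS} groups"
        )
    n_halvings = int(round(np.log2(1.0 / stop_fraction)))
    sizes = []
    size = full_n
    for k in range(n_halvings + 1):
        sizes.append(size)
        if size % 2 and k < n_halvings:
            logger.warning("size %d not divisible by 2; flooring", size)
        size //= 2
    return sizes


def partition_five(n: int, seed: int) -> FoldAssignment:
    """Uniform random permutation then round-robin into five groups."""
    if n < N_GROUPS:
        raise InvalidInputError(f"need at least {N_GROUPS} records, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[perm] = np.arange(n) % N_GROUPS
    return FoldAssignment(labels=labels, seed=seed)


def run_cv(
    records: pd.DataFrame,
    config: RefinerConfig = RefinerConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Five-fold rotation: train on four groups, evaluate the fifth.

    Returns a DataFrame with one row per input record (original order):
    ``eye_id``, ``error_d`` (refined prediction − MRSE), ``fold``.
    """
    records = records.reset_index(drop=True)
    assignment = partition_five(len(records), seed)
    errors = np.full(len(records), np.nan)
    for fold in range(N_GROUPS):
        hold = assignment.labels == fold
        train_df = records.loc[~hold]
        eval_df = records.loc[hold]
        try:
            model = refine.train_refiner(train_df, config)
        except Exception as exc:
            raise InvalidInputError(f"training failed in fold {fold}: {exc}") from exc
        refined = refine.refine(model, eval_df)
        errors[hold] = metrics.prediction_error(
            refined, eval_df["mrse_d"].to_numpy()
        )
    assert not np.any(np.isnan(errors))
    return pd.DataFrame(
        {
            "eye_id": records["eye_id"],
            "error_d": errors,
            "fold": assignment.labels,
        }
    )


def _child_seed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


def run_ablation(
    cohort: pd.DataFrame,
    plan: Optional[AblationPlan] = None,
    config: RefinerConfig = RefinerConfig(),
    size_configs: Optional[dict] = None,
) -> AblationResult:
    """Run the five-group rotation at every size of the halving schedule.

    In nested mode (default) each smaller dataset is a prefix of one fixed
    random permutation of the cohort, so the 75-eye dataset is a subset of
    the 150-eye dataset, and so on; independent mode redraws each subset.
    ``size_configs`` optionally overrides the refiner configuration for
    specific sizes (e.g. a reduced grid at the largest sizes).
    """
    plan = plan or AblationPlan.from_cohort_size(len(cohort))
    if plan.sizes[0] != len(cohort):
        raise InvalidConfigError(
            f"cohort size {len(cohort)} != first plan size {plan.sizes[0]}"
        )
    cohort = cohort.reset_index(drop=True)
    master = np.random.default_rng(_child_seed(plan.seed, 0)).permutation(len(cohort))
    errors = {}
    summaries = {}
    train_sizes = {}
    for i, size in enumerate(plan.sizes):
        if plan.nested:
            idx = master[:size]
        else:
            idx = np.random.default_rng(
                _child_seed(plan.seed, 1, i)
            ).permutation(len(cohort))[:size]
        subset = cohort.iloc[np.sort(idx)].reset_index(drop=True)
        cfg = (size_configs or {}).get(size, config)
        res = run_cv(subset, cfg, seed=_child_seed(plan.seed, 2, i))
        errors[size] = res[["eye_id", "error_d"]]
        summaries[size] = metrics.summarize(res["error_d"].to_numpy())
        # training size = records outside the largest hold-out group
        train_sizes[size] = size - int(np.ceil(size / N_GROUPS))
    return AblationResult(
        sizes=list(plan.sizes),
        errors=errors,
        summaries=summaries,
        train_sizes=train_sizes,
        provenance={
            "seed": plan.seed,
            "nested": plan.nested,
            "sizes": list(plan.sizes),
            "repartitioned_per_size": True,
        },
    )


def subgroup_axl(
    errors: pd.DataFrame, cohort: pd.DataFrame
) -> dict:
    """Split evaluation errors into long (AXL > 26.0 mm) and normal
    (22.0 <= AXL <= 26.0 mm) eyes; short eyes (< 22.0 mm) are excluded and
    only counted. Empty subgroups are reported as None, never fabricated."""
    merged = errors.merge(cohort[["eye_id", "axl_mm"]], on="eye_id")
    long_mask = merged["axl_mm"] > 26.0
    normal_mask = (merged["axl_mm"] >= 22.0) & (merged["axl_mm"] <= 26.0)
    short_mask = merged["axl_mm"] < 22.0
    out = {"n_short_excluded": int(short_mask.sum())}
    for name, mask in (("long", long_mask), ("normal", normal_mask)):
        vals = merged.loc[mask, "error_d"].to_numpy()
        if vals.size == 0:
            logger.warning("AXL subgroup %r is empty; summary undefined", name)
            out[name] = None
        else:
            out[name] = metrics.summarize(vals)
    return out


def subgroup_aconstant(
    errors: pd.DataFrame,
    cohort: pd.DataFrame,
    edges: tuple = (119.0, 119.2, 119.4, 119.6),
) -> dict:
    """Per-A-constant-bin error summaries.

    Bins are right-closed: (-inf, e1], (e1, e2], ...; records above the last
    edge are excluded with a warning.
    """
    merged = errors.merge(cohort[["eye_id", "a_constant"]], on="eye_id")
    a = merged["a_constant"].to_numpy()
    above = a > edges[-1]
    if np.any(above):
        logger.warning(
            "%d record(s) with a_constant above %.2f excluded",
            int(above.sum()), edges[-1],
        )
    out = {}
    lowers = (-np.inf,) + tuple(edges[:-1])
    for lo, hi in zip(lowers, edges):
        label = f"<= {hi:.1f}" if np.isinf(lo) else f"({lo:.1f}, {hi:.1f}]"
        mask = (a > lo) & (a <= hi)
        vals = merged.loc[mask, "error_d"].to_numpy()
        out[label] = metrics.summarize(vals) if vals.size else None
    return out
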