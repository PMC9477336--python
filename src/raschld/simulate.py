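"""Generators for dichotomous Rasch data with controlled local dependence.

Two violations of local independence are emulated, following the
Marais–Andrich generating models:

* **Trait dependence (TD)** — multidimensionality.  Items are organised in
  subsets; the effective trait for person ``p`` on subset ``s`` is
  ``theta_ps = theta_p + c * theta'_ps`` where ``theta_p`` is the primary
  trait, ``theta'_ps`` a subset-specific trait, and ``c >= 0`` the magnitude
  of the violation.  All traits are independent standard normal, so the
  correlation between the effective traits of any two subsets is
  ``1 / (1 + c^2)``.

* **Response dependence (RD)** — a direct statistical dependence.  The first
  ("halo") item of each subset follows the ordinary Rasch model; every other
  item ``j`` in the subset becomes easier by ``d`` (difficulty ``b_j - d``)
  when the halo response was 1 and harder by ``d`` (``b_j + d``) when it
  was 0.

With ``c = 0`` or ``d = 0`` both generators reduce to an ordinary
unidimensional Rasch simulation.

Item difficulties are ``I`` equally spaced values on ``[-2, 2]``.  The
ascending grid is cut into consecutive blocks of ``subset_size`` items and
each block is rotated so that its hardest item comes first: the first item
of every subset is the hardest one and acts as the halo item under RD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulationCondition",
    "TrueParameters",
    "ResponseMatrix",
    "trait_correlation",
    "rasch_probability",
    "difficulty_grid",
    "simulate",
    "simulate_td",
    "simulate_rd",
    "write_response_matrix",
    "read_response_matrix",
]

_LD_TYPES = ("none", "TD", "RD")

#: attempts at regenerating a replication that produced a constant item
_MAX_REGENERATIONS = 100


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design.

    Parameters
    ----------
    ld_type:
        ``"none"``, ``"TD"`` (trait dependence) or ``"RD"`` (response
        dependence).  ``"none"`` is equivalent to TD or RD at magnitude 0.
    magnitude:
        The violation magnitude: ``c`` for TD, ``d`` for RD.  Any
        non-negative real is accepted; the replication study uses {0, 1, 2}.
    n_items, n_persons:
        Test length ``I`` and sample size ``N``.  ``n_items`` must be a
        multiple of ``subset_size``.
    subset_size:
        Items per dependent subset (default 5).
    seed:
        Integer seed; identical conditions produce bit-identical data.
    """

    ld_type: str = "none"
    magnitude: float = 0.0
    n_items: int = 30
    n_persons: int = 250
    subset_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ld_type not in _LD_TYPES:
            raise ValueError(
                f"ld_type must be one of {_LD_TYPES}, got {self.ld_type!r}"
            )
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.n_items < 2 or self.n_persons < 1 or self.subset_size < 1:
            raise ValueError("n_items, n_persons and subset_size must be positive")
        if self.n_items % self.subset_size:
            raise ValueError(
                f"n_items ({self.n_items}) must be divisible by "
                f"subset_size ({self.subset_size})"
            )

    @property
    def n_subsets(self) -> int:
        return self.n_items // self.subset_size


@dataclass
class TrueParameters:
    """Generating parameters of one replication (ground truth for RMSE)."""

    theta: np.ndarray            # (N,) primary trait
    theta_subset: np.ndarray     # (N, S) subset-specific traits (TD only; zeros for RD)
    difficulties: np.ndarray     # (I,) b_i, a permutation of the [-2, 2] grid
    subset_of_item: np.ndarray   # (I,) subset index of each item
    halo_flag: np.ndarray        # (I,) True for the first (hardest) item of a subset


@dataclass
class ResponseMatrix:
    """An ``N x I`` binary response matrix plus metadata.

    ``truth`` is ``None`` when the matrix was read from user data rather
    than simulated.  ``regenerations`` counts how many draws were discarded
    because some item came out with a single response category.
    """

    data: np.ndarray
    condition: Optional[SimulationCondition] = None
    truth: Optional[TrueParameters] = None
    regenerations: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("response data must be a 2-D persons x items array")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("responses must be 0/1 with no missing values")
        self.data = self.data.astype(np.int8)

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


def trait_correlation(c: float) -> float:
    """Inter-subset correlation of effective traits under TD, ``1/(1+c^2)``.

    At c = 0, 1, 2 this gives 1.0, 0.5 and 0.2: the degree to which the
    subsets still measure one common trait.
    """
    if c < 0:
        raise ValueError("trait-dependence magnitude c must be non-negative")
    return 1.0 / (1.0 + c * c)


def rasch_probability(theta, b):
    """Rasch success probability ``exp(theta-b) / (1 + exp(theta-b))``."""
    return expit(np.asarray(theta, dtype=float) - np.asarray(b, dtype=float))


def difficulty_grid(n_items: int, subset_size: int = 5):
    """Item difficulties, subset membership and halo flags.

    The ``I`` difficulties are equally spaced on [-2, 2]
    (``b_k = -2 + 4(k-1)/(I-1)``).  The ascending grid is split into
    consecutive blocks of ``subset_size``; each block is rotated so its
    maximum comes first, making the first item of every subset the hardest.

    Returns
    -------
    (difficulties, subset_of_item, halo_flag)
    """
    if n_items % subset_size:
        raise ValueError("n_items must be divisible by subset_size")
    grid = np.linspace(-2.0, 2.0, n_items)
    n_subsets = n_items // subset_size
    blocks = grid.reshape(n_subsets, subset_size)
    # ascending block -> [hardest, rest...]
    b = np.column_stack([blocks[:, -1], blocks[:, :-1]]).ravel()
    subset_of_item = np.repeat(np.arange(n_subsets), subset_size)
    halo = np.zeros(n_items, dtype=bool)
    halo[::subset_size] = True
    return b, subset_of_item, halo


def _rng_for_attempt(condition: SimulationCondition, attempt: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(condition.seed), spawn_key=(attempt,))
    return np.random.default_rng(ss)


def _draw_td(condition: SimulationCondition, rng: np.random.Generator):
    c = float(condition.magnitude)
    n, n_sub = condition.n_persons, condition.n_subsets
    b, subset_of_item, halo = difficulty_grid(condition.n_items, condition.subset_size)
    theta = rng.standard_normal(n)
    theta_subset = rng.standard_normal((n, n_sub))
    theta_eff = theta[:, None] + c * theta_subset        # (N, S)
    prob = expit(theta_eff[:, subset_of_item] - b[None, :])
    x = (rng.random((n, condition.n_items)) < prob).astype(np.int8)
    truth = TrueParameters(theta, theta_subset, b, subset_of_item, halo)
    return x, truth


def _draw_rd(condition: SimulationCondition, rng: np.random.Generator):
    d = float(condition.magnitude)
    n, n_sub = condition.n_persons, condition.n_subsets
    b, subset_of_item, halo = difficulty_grid(condition.n_items, condition.subset_size)
    theta = rng.standard_normal(n)
    u = rng.random((n, condition.n_items))
    x = np.empty((n, condition.n_items), dtype=np.int8)
    halo_idx = np.flatnonzero(halo)
    x[:, halo_idx] = u[:, halo_idx] < expit(theta[:, None] - b[halo_idx][None, :])
    # dependent items shift difficulty by -d / +d given the subset's halo response
    dep_idx = np.flatnonzero(~halo)
    halo_of_dep = halo_idx[subset_of_item[dep_idx]]
    shift = np.where(x[:, halo_of_dep] == 1, -d, d)      # (N, n_dep)
    prob = expit(theta[:, None] - (b[dep_idx][None, :] + shift))
    x[:, dep_idx] = u[:, dep_idx] < prob
    truth = TrueParameters(theta, np.zeros((n, n_sub)), b, subset_of_item, halo)
    return x, truth


def simulate(condition: SimulationCondition) -> ResponseMatrix:
    """Simulate a response matrix for any condition.

    ``ld_type="none"`` uses the TD path with magnitude forced to 0.  If a
    draw yields an item with a single response category (which breaks both
    tetrachoric estimation and conditional ML), the whole replication is
    redrawn from the next derived seed; the count is recorded.
    """
    if condition.ld_type == "RD":
        draw = _draw_rd
    else:
        draw = _draw_td
        if condition.ld_type == "none" and condition.magnitude != 0:
            condition = replace(condition, magnitude=0.0)
    for attempt in range(_MAX_REGENERATIONS):
        rng = _rng_for_attempt(condition, attempt)
        x, truth = draw(condition, rng)
        col_sums = x.sum(axis=0)
        if ((col_sums > 0) & (col_sums < condition.n_persons)).all():
            return ResponseMatrix(x, condition, truth, regenerations=attempt)
    raise RuntimeError(
        f"could not simulate a non-degenerate matrix in {_MAX_REGENERATIONS} "
        f"attempts for condition {condition}"
    )


def simulate_td(condition: SimulationCondition) -> ResponseMatrix:
    """Trait-dependence simulation (``P(X=1) = logistic(theta_p + c*theta'_ps - b_i)``)."""
    if condition.ld_type == "RD":
        raise ValueError("simulate_td requires ld_type 'TD' or 'none'")
    if condition.ld_type == "none":
        condition = replace(condition, ld_type="TD", magnitude=0.0)
    return simulate(condition)


def simulate_rd(condition: SimulationCondition) -> ResponseMatrix:
    """Response-dependence simulation (halo-conditional difficulty shifts)."""
    if condition.ld_type == "TD":
        raise ValueError("simulate_rd requires ld_type 'RD' or 'none'")
    if condition.ld_type == "none":
        condition = replace(condition, ld_type="RD", magnitude=0.0)
    return simulate(condition)


# ---------------------------------------------------------------------------
# plain-text round trip: CSV matrix + JSON sidecar


def write_response_matrix(matrix: ResponseMatrix, prefix) -> None:
    """Write ``<prefix>.csv`` (persons x items, 0/1) and ``<prefix>.json``.

    The sidecar records the condition and, when present, the generating
    parameters, so a replication is fully regenerable and auditable.
    """
    prefix = Path(prefix)
    labels = [f"item{j + 1:03d}" for j in range(matrix.n_items)]
    pd.DataFrame(matrix.data, columns=labels).to_csv(
        prefix.with_suffix(".csv"), index=False
    )
    meta: dict = {"regenerations": matrix.regenerations}
    if matrix.condition is not None:
        meta["condition"] = {
            "ld_type": matrix.condition.ld_type,
            "magnitude": matrix.condition.magnitude,
            "n_items": matrix.condition.n_items,
            "n_persons": matrix.condition.n_persons,
            "subset_size": matrix.condition.subset_size,
            "seed": matrix.condition.seed,
        }
    if matrix.truth is not None:
        t = matrix.truth
        meta["truth"] = {
            "theta": t.theta.tolist(),
            "theta_subset": t.theta_subset.tolist(),
            "difficulties": t.difficulties.tolist(),
            "subset_of_item": t.subset_of_item.tolist(),
            "halo_flag": t.halo_flag.astype(int).tolist(),
        }
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def read_response_matrix(prefix) -> ResponseMatrix:
    """Read a matrix written by :func:`write_response_matrix`.

    A bare CSV with no sidecar is accepted (user-data mode): ``condition``
    and ``truth`` are then ``None``.
    """
    prefix = Path(prefix)
    data = pd.read_csv(prefix.with_suffix(".csv")).to_numpy()
    condition = truth = None
    regenerations = 0
    sidecar = prefix.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        regenerations = meta.get("regenerations", 0)
        if "condition" in meta:
            condition = SimulationCondition(**meta["condition"])
        if "truth" in meta:
            t = meta["truth"]
            truth = TrueParameters(
                theta=np.asarray(t["theta"], dtype=float),
                theta_subset=np.asarray(t["theta_subset"], dtype=float),
                difficulties=np.asarray(t["difficulties"], dtype=float),
                subset_of_item=np.asarray(t["subset_of_item"], dtype=int),
                halo_flag=np.asarray(t["halo_flag"], dtype=bool),
            )
    return ResponseMatrix(data, condition, truth, regenerations=regenerations)
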