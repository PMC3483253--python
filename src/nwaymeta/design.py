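"""Experimental designs over discrete parameter levels.

Two generators are provided:

* :func:`make_ombr_design` - the optimised multi-level binary replacement
  (OMBR) design.  Each factor with L = 2^b equally spaced levels is replaced
  by b binary "replacement bits"; every bit is assigned a non-zero GF(2)
  linear combination (a *mask*) of k independent base bits, and the design is
  the image of the full 2^k two-level factorial under those masks.  Requiring
  each factor's b masks to be linearly independent guarantees perfect level
  balance (every level appears exactly 2^k / L times); requiring the whole
  mask matrix to have rank k guarantees all 2^k rows are distinct.  The
  confounding pattern (the mask assignment) is "optimised" by a documented
  heuristic: draw a fixed number of random feasible assignments and keep the
  one minimising the maximum absolute pairwise correlation among the factor
  level columns (deterministic given ``optimizer_seed``).

* :func:`make_mc_design` - Monte-Carlo test designs drawing each cell
  independently and uniformly from the factor's discrete level set.

A full factorial of 9 factors at 8 levels would need 8^9 > 134 million runs;
the default 9-factor OMBR configuration (k = 13) compresses this to 8192
runs while keeping each factor balanced (1024 runs per level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .tensorio import ParameterTable

__all__ = [
    "FactorSpec", "OMBRSpec", "make_levels", "make_ombr_design",
    "make_mc_design", "circadian_clock_factors", "goodwin_demo_factors",
    "save_ombr_spec", "load_ombr_spec",
]


@dataclass(frozen=True)
class FactorSpec:
    """One designed input parameter: name, range and level count (power of 2)."""

    name: str
    min: float
    max: float
    n_levels: int

    def __post_init__(self) -> None:
        if self.max <= self.min:
            raise ValueError(f"{self.name}: max must exceed min")
        if self.n_levels < 2 or self.n_levels & (self.n_levels - 1):
            raise ValueError(f"{self.name}: n_levels must be a power of 2, got {self.n_levels}")

    @property
    def bits(self) -> int:
        return int(np.log2(self.n_levels))


def make_levels(f: FactorSpec) -> np.ndarray:
    """Equally spaced levels from min to max inclusive."""
    return np.linspace(f.min, f.max, f.n_levels)


@dataclass
class OMBRSpec:
    """A fully resolved OMBR design: factors, run exponent and bit masks.

    ``masks[i]`` is the list of GF(2) mask integers (bits over the k base
    columns) for factor i's replacement bits, least-significant level bit
    first.  Level index of a run r (0..2^k-1) for factor i is
    sum_b popcount(r & masks[i][b]) % 2 << b  (plain binary bit-to-level
    code, fixed).
    """

    factors: list[FactorSpec]
    run_exponent: int
    masks: list[list[int]] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return 2 ** self.run_exponent


def _gf2_rank(vectors: list[int]) -> int:
    rank = 0
    pivots: list[int] = []
    for v in vectors:
        for p in pivots:
            v = min(v, v ^ p)
        if v:
            pivots.append(v)
            rank += 1
    return rank


def _level_columns(masks: list[list[int]], k: int) -> np.ndarray:
    """Level-index column per factor for all 2^k runs, vectorised over runs."""
    runs = np.arange(2 ** k, dtype=np.uint32)
    base_bits = ((runs[:, None] >> np.arange(k)) & 1).astype(np.uint8)  # (n_runs, k)
    cols = []
    for factor_masks in masks:
        level = np.zeros(len(runs), dtype=np.int64)
        for b, mask in enumerate(factor_masks):
            mask_bits = np.array([(mask >> j) & 1 for j in range(k)], dtype=np.uint8)
            bit = base_bits @ mask_bits % 2
            level += bit.astype(np.int64) << b
        cols.append(level)
    return np.column_stack(cols)


def _random_masks(factors: Sequence[FactorSpec], k: int, rng: np.random.Generator) -> list[list[int]]:
    """Draw a feasible mask assignment: per-factor independence + overall rank k."""
    for _ in range(200):
        masks: list[list[int]] = []
        ok = True
        for f in factors:
            for _ in range(50):
                cand = [int(rng.integers(1, 2 ** k)) for _ in range(f.bits)]
                if _gf2_rank(cand) == f.bits:
                    masks.append(cand)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        flat = [m for fm in masks for m in fm]
        if _gf2_rank(flat) == min(k, len(flat)):
            return masks
    raise RuntimeError("could not draw a feasible OMBR confounding pattern")


def make_ombr_design(
    spec: OMBRSpec,
    optimizer_seed: int = 0,
    n_trials: int = 32,
) -> ParameterTable:
    """Generate the balanced OMBR design for ``spec``.

    Among ``n_trials`` random feasible confounding patterns, the one with the
    smallest maximum absolute pairwise correlation between factor level
    columns is kept (deterministic under ``optimizer_seed``).  The winning
    masks are written back to ``spec.masks`` so the design can be reproduced
    exactly.
    """
    k = spec.run_exponent
    total_bits = sum(f.bits for f in spec.factors)
    if k < max(f.bits for f in spec.factors):
        raise ValueError("run_exponent must be at least the largest bits-per-factor")
    if k > total_bits:
        raise ValueError(
            f"run_exponent {k} exceeds total replacement bits {total_bits}: "
            "the design cannot have more independent columns than bits"
        )
    if spec.masks:
        # a serialised confounding pattern: reproduce the design exactly
        levels = _level_columns(spec.masks, k)
        values = np.column_stack(
            [make_levels(f)[levels[:, i]] for i, f in enumerate(spec.factors)]
        )
        ranges = {f.name: (f.min, f.max, f.n_levels) for f in spec.factors}
        return ParameterTable(values, [f.name for f in spec.factors], ranges,
                              [f"run{r}" for r in range(spec.n_runs)])
    rng = np.random.default_rng(optimizer_seed)
    best: tuple[float, list[list[int]], np.ndarray] | None = None
    for _ in range(n_trials):
        masks = _random_masks(spec.factors, k, rng)
        levels = _level_columns(masks, k)
        if levels.shape[1] > 1:
            corr = np.corrcoef(levels, rowvar=False)
            score = float(np.abs(corr[np.triu_indices_from(corr, 1)]).max())
        else:
            score = 0.0
        if best is None or score < best[0]:
            best = (score, masks, levels)
        if score == 0.0:
            break
    assert best is not None
    _, masks, levels = best
    spec.masks = masks

    values = np.column_stack(
        [make_levels(f)[levels[:, i]] for i, f in enumerate(spec.factors)]
    )
    ranges = {f.name: (f.min, f.max, f.n_levels) for f in spec.factors}
    return ParameterTable(values, [f.name for f in spec.factors], ranges,
                          [f"run{r}" for r in range(spec.n_runs)])


def make_mc_design(
    specs: Sequence[FactorSpec],
    n_runs: int,
    seed: int = 0,
) -> ParameterTable:
    """Monte-Carlo design: cells drawn uniformly from each factor's levels."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    cols = []
    for f in specs:
        levels = make_levels(f)
        cols.append(levels[rng.integers(0, f.n_levels, size=n_runs)])
    ranges = {f.name: (f.min, f.max, f.n_levels) for f in specs}
    return ParameterTable(np.column_stack(cols), [f.name for f in specs], ranges,
                          [f"mc{r}" for r in range(n_runs)])


# ---------------------------------------------------------------------------
# built-in factor sets
# ---------------------------------------------------------------------------

def circadian_clock_factors() -> list[FactorSpec]:
    """Nine rate parameters of a 16-state mammalian circadian clock model,
    8 equally spaced levels each, spanning ranges wide enough to cover
    qualitatively different oscillatory behaviours.

    Levels are always derived from (min, max, n_levels); rounded step-size
    displays are never used.
    """
    ranges = [
        ("v_mB", 0.02, 0.38),    # max rate of Bmal1 mRNA degradation (nM/h)
        ("v_mC", 0.95, 1.54),    # max rate of Cry mRNA degradation (nM/h)
        ("v_mP", 0.98, 2.09),    # max rate of Per mRNA degradation (nM/h)
        ("v_dPCN", 0.99, 1.14),  # max degradation rate, nuclear phosph. Per-Cry (nM/h)
        ("v_dIN", 0.08, 1.52),   # max degradation rate, nuclear Per-Cry-Clock-Bmal1 (nM/h)
        ("k_1", 0.08, 1.52),     # Per-Cry nuclear entry (1/h)
        ("k_3", 0.08, 1.52),     # Per-Cry complex formation (1/(nM h))
        ("k_5", 0.27, 0.41),     # Bmal1 nuclear entry (1/h)
        ("k_7", 0.05, 0.95),     # inactive Per-Cry-Clock-Bmal1 formation (1/(nM h))
    ]
    return [FactorSpec(name, lo, hi, 8) for name, lo, hi in ranges]


def goodwin_demo_factors(n_levels: int = 4) -> list[FactorSpec]:
    """Design ranges for the built-in Goodwin demo oscillator (oscillatory
    throughout the box at the default Hill coefficient h = 10)."""
    return [
        FactorSpec("v1", 0.7, 1.3, n_levels),
        FactorSpec("v2", 0.7, 1.3, n_levels),
        FactorSpec("d1", 0.06, 0.14, n_levels),
        FactorSpec("d2", 0.06, 0.14, n_levels),
    ]


def save_ombr_spec(spec: OMBRSpec, path: str | Path) -> None:
    payload = {
        "run_exponent": spec.run_exponent,
        "factors": [
            {"name": f.name, "min": f.min, "max": f.max, "n_levels": f.n_levels}
            for f in spec.factors
        ],
        "masks": spec.masks,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ombr_spec(path: str | Path) -> OMBRSpec:
    payload = json.loads(Path(path).read_text())
    factors = [FactorSpec(**f) for f in payload["factors"]]
    return OMBRSpec(factors, payload["run_exponent"], payload.get("masks", []))
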