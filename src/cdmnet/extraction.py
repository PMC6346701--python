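"""Conserved disease module extraction from the multilayer tensor.

A conserved disease module (CDM) is a disease set whose induced subgraph is
heavy in *every* layer of the multilayer network. With disease membership
vector x and layer membership vector y, the module weight is

    H_A(x, y) = 1/2 * sum_{i,j,k} a_ijk * x_i * x_j * y_k,

and modules are found by maximizing H_A over nonnegative x, y under p-norm
constraints ||x||_p = 1, ||y||_q = 1 (a tensor power-method style
multiplicative update), then discretizing x into a member set, masking the
found module out of the tensor, and repeating. An exhaustive small-instance
solver serves as an independent oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .layers import MultilayerTensor

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "MembershipVectors",
    "ConservedDiseaseModule",
    "module_weight",
    "binary_module_weight",
    "solve_continuous",
    "discretize",
    "mask_module",
    "extract_all_cdms",
    "brute_force_heaviest",
]


@dataclass(frozen=True)
class SolverConfig:
    """Knobs of the continuous solver and the module thresholds.

    p, q are the norm exponents of the constraints on x and y. p = q = 2
    gives the classical tensor power iteration but leaves x diffuse on
    unstructured backgrounds; the default p = 1.5 pushes the constraint
    toward l1 so x concentrates on a genuinely dense disease core
    (``support_frac`` then cuts the negligible tail before
    discretization). min_size and min_weight are the module acceptance
    thresholds: at least 5 diseases, and induced edge-weight sum of at
    least 0.3 *in every layer* — a conserved module must be heavy in each
    of its appearances, not merely in the cross-layer total. max_size
    bounds the discretization search space: the underlying combinatorial
    problem is fixed-size heaviest-subgraph search, and without a bound a
    diffuse continuous solution can sprawl into a large low-density set
    that crosses the weight threshold on background noise alone.
    """

    p: float = 1.5
    q: float = 2.0
    max_iter: int = 200
    tol: float = 1e-9
    n_restarts: int = 10
    seed: int = 0
    min_size: int = 5
    max_size: int = 30
    min_weight: float = 0.3
    max_modules: int = 20
    jitter: float = 0.05
    support_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.p <= 1 or self.q <= 1:
            raise ValueError("norm exponents p, q must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.min_size < 1 or self.min_weight < 0:
            raise ValueError("invalid module thresholds")
        if self.max_size < self.min_size:
            raise ValueError("max_size must be >= min_size")


@dataclass
class MembershipVectors:
    """Continuous solver output: membership vectors and the ascent trace."""

    x: np.ndarray
    y: np.ndarray
    objective: float
    converged: bool
    history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ConservedDiseaseModule:
    """A discretized module: member diseases and their induced weights."""

    module_id: str
    members: tuple[str, ...]
    per_layer_weight: dict[str, float]
    total_weight: float

    def __post_init__(self) -> None:
        total = sum(self.per_layer_weight.values())
        if not np.isclose(total, self.total_weight):
            raise ValueError("total_weight must equal the sum of per-layer weights")

    @property
    def size(self) -> int:
        return len(self.members)


def module_weight(x: np.ndarray, y: np.ndarray, tensor: MultilayerTensor) -> float:
    """Evaluate H_A(x, y) = 1/2 sum a_ijk x_i x_j y_k."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (tensor.n,) or y.shape != (tensor.m,):
        raise ValueError(
            f"expected x of length {tensor.n} and y of length {tensor.m}, "
            f"got {x.shape} and {y.shape}"
        )
    w = tensor.values @ y  # (n, n) layer-combined adjacency
    return float(0.5 * x @ w @ x)


def binary_module_weight(
    members, tensor: MultilayerTensor
) -> tuple[dict[str, float], float]:
    """Per-layer and total induced edge-weight sums of a member set (y = all ones)."""
    ix = tensor.indices(members)
    block = tensor.values[np.ix_(ix, ix)]
    per_layer_vals = block.sum(axis=(0, 1)) / 2.0
    per_layer = {
        layer: float(per_layer_vals[k]) for k, layer in enumerate(tensor.layer_order)
    }
    return per_layer, float(per_layer_vals.sum())


def _p_normalize(v: np.ndarray, p: float) -> np.ndarray:
    norm = float(np.sum(v**p) ** (1.0 / p))
    if norm == 0:
        raise ZeroDivisionError
    return v / norm


def solve_continuous(
    tensor: MultilayerTensor,
    config: SolverConfig | None = None,
    allowed: np.ndarray | None = None,
) -> MembershipVectors:
    """Maximize H_A over nonnegative x, y with ||x||_p = ||y||_q = 1.

    Alternating multiplicative updates:

        x_i <- (sum_{j,k} a_ijk x_j y_k)^(1/(p-1)),  renormalized to ||x||_p = 1
        y_k <- (1/2 sum_{i,j} a_ijk x_i x_j)^(1/(q-1)), renormalized to ||y||_q = 1

    Strictly positive starts (uniform plus seeded jitter) are required
    because multiplicative updates preserve zeros. The objective trace is
    non-decreasing: a step that would lower H_A (possible when the
    layer-combined adjacency is indefinite) stops the iteration at the
    previous iterate. Best of ``n_restarts`` seeded restarts is returned.

    ``allowed`` optionally restricts x support to a boolean node mask.
    """
    config = config or SolverConfig()
    values = tensor.values
    if not np.any(values):
        raise ValueError("tensor is all-zero; nothing to extract")
    n, m = tensor.n, tensor.m
    mask = np.ones(n, dtype=bool) if allowed is None else np.asarray(allowed, dtype=bool)
    if not mask.any():
        raise ValueError("allowed mask excludes every node")
    rng = np.random.default_rng(config.seed)
    exp_x = 1.0 / (config.p - 1.0)
    exp_y = 1.0 / (config.q - 1.0)
    best: MembershipVectors | None = None

    for _ in range(config.n_restarts):
        x = np.where(mask, 1.0 + config.jitter * rng.random(n), 0.0)
        y = 1.0 + config.jitter * rng.random(m)
        x = _p_normalize(x, config.p)
        y = _p_normalize(y, config.q)
        h_prev = module_weight(x, y, tensor)
        history = [h_prev]
        converged = False
        for _ in range(config.max_iter):
            w = values @ y
            x_raw = w @ x
            x_raw[~mask] = 0.0
            y_raw = 0.5 * np.einsum("ijk,i,j->k", values, x, x)
            try:
                x_new = _p_normalize(np.maximum(x_raw, 0.0) ** exp_x, config.p)
            except ZeroDivisionError:
                converged = True
                break
            y_raw2 = 0.5 * np.einsum("ijk,i,j->k", values, x_new, x_new)
            try:
                y_new = _p_normalize(np.maximum(y_raw2, 0.0) ** exp_y, config.q)
            except ZeroDivisionError:
                converged = True
                break
            h_new = module_weight(x_new, y_new, tensor)
            if h_new < h_prev - config.tol:
                # ascent safeguard: keep the previous iterate
                converged = True
                break
            x, y = x_new, y_new
            history.append(h_new)
            if abs(h_new - h_prev) < config.tol:
                converged = True
                break
            h_prev = h_new
        if not converged:
            logger.warning("solver did not converge within %d iterations", config.max_iter)
        cand = MembershipVectors(x, y, history[-1], converged, history)
        if best is None or cand.objective > best.objective:
            best = cand
    assert best is not None
    return best


def discretize(
    x: np.ndarray,
    y: np.ndarray,
    tensor: MultilayerTensor,
    config: SolverConfig | None = None,
    allowed: np.ndarray | None = None,
    module_id: str = "CDM",
) -> ConservedDiseaseModule | None:
    """Turn a continuous membership vector into a module, or ``None``.

    Only diseases inside the solver's support (x >= support_frac * max x)
    are candidates; they are ranked by x (descending, node id as
    tie-break) and every prefix of size min_size..max_size is scored by
    its binary induced weight (y = all ones). The prefix with the highest
    weight per member is the candidate module; it is returned only if its
    induced weight reaches ``min_weight`` in every layer. The support
    cutoff, the density peak and the per-layer threshold together reject
    diffuse background: a sprawling low-density set can accumulate weight
    from many tiny edges spread across layers, but it is neither the
    weight-per-member maximizer nor heavy in each layer separately.
    """
    config = config or SolverConfig()
    x = np.asarray(x, dtype=float)
    n = tensor.n
    mask = np.ones(n, dtype=bool) if allowed is None else np.asarray(allowed, dtype=bool)
    cutoff = config.support_frac * (x[mask].max() if mask.any() else 0.0)
    candidates = [i for i in range(n) if mask[i] and x[i] >= cutoff and x[i] > 0]
    candidates.sort(key=lambda i: (-x[i], tensor.node_order[i]))
    if len(candidates) < config.min_size:
        return None

    combined = tensor.values.sum(axis=2)  # (n, n) summed over layers
    best_size, best_density, best_weight = None, -np.inf, 0.0
    weight = 0.0
    chosen: list[int] = []
    for rank, i in enumerate(candidates):
        if chosen:
            weight += combined[i, chosen].sum()
        chosen.append(i)
        size = rank + 1
        if size > config.max_size:
            break
        if size < config.min_size:
            continue
        density = weight / size
        if density > best_density:
            best_density, best_size, best_weight = density, size, weight
    if best_size is None:
        return None
    members = tuple(sorted(tensor.node_order[i] for i in candidates[:best_size]))
    per_layer, total = binary_module_weight(members, tensor)
    if min(per_layer.values()) < config.min_weight:
        return None
    return ConservedDiseaseModule(module_id, members, per_layer, total)


def mask_module(tensor: MultilayerTensor, module: ConservedDiseaseModule) -> MultilayerTensor:
    """Zero all intra-module entries in every layer; everything else untouched."""
    out = tensor.copy()
    ix = out.indices(module.members)
    out.values[np.ix_(ix, ix)] = 0.0
    return out


def extract_all_cdms(
    tensor: MultilayerTensor, config: SolverConfig | None = None
) -> list[ConservedDiseaseModule]:
    """Iterate solve -> discretize -> mask until no module passes the thresholds.

    Later rounds exclude already-assigned diseases, so the returned modules
    are pairwise disjoint. Extraction order is reported as found; total
    weights are logged (typically, but not necessarily, decreasing).
    """
    config = config or SolverConfig()
    current = tensor
    allowed = np.ones(tensor.n, dtype=bool)
    modules: list[ConservedDiseaseModule] = []
    for round_no in range(config.max_modules):
        if allowed.sum() < config.min_size or not np.any(current.values):
            break
        round_config = replace(config, seed=config.seed + round_no)
        try:
            sol = solve_continuous(current, round_config, allowed=allowed)
        except ValueError:
            break
        module = discretize(
            sol.x,
            sol.y,
            current,
            round_config,
            allowed=allowed,
            module_id=f"CDM{len(modules) + 1}",
        )
        if module is None:
            break
        modules.append(module)
        logger.info(
            "extracted %s: %d diseases, total weight %.4f",
            module.module_id,
            module.size,
            module.total_weight,
        )
        current = mask_module(current, module)
        allowed[current.indices(module.members)] = False
    return modules


def brute_force_heaviest(
    tensor: MultilayerTensor, size: int
) -> tuple[tuple[str, ...], float]:
    """Exhaustive heaviest fixed-size module (test oracle; n <= 15 only).

    Ties are broken toward the lexicographically first member tuple.
    """
    if tensor.n > 15:
        raise ValueError(f"brute force limited to n <= 15, got n = {tensor.n}")
    if not 1 <= size <= tensor.n:
        raise ValueError(f"size must be in [1, {tensor.n}]")
    combined = tensor.values.sum(axis=2)
    order = sorted(range(tensor.n), key=lambda i: tensor.node_order[i])
    best_members: tuple[str, ...] | None = None
    best_weight = -np.inf
    for combo in combinations(order, size):
        ix = np.asarray(combo)
        w = float(combined[np.ix_(ix, ix)].sum() / 2.0)
        members = tuple(tensor.node_order[i] for i in combo)
        if w > best_weight or (w == best_weight and members < best_members):
            best_weight, best_members = w, members
    assert best_members is not None
    return best_members, best_weight
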