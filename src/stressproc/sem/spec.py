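"""RAM model specification and implied-covariance algebra.

Variables are ordered observed-first, latent-last.  The path matrix ``A``
holds a coefficient in row *target*, column *source*; ``S`` holds
exogenous variances/covariances and residual variances; the filter ``F``
selects the observed rows.  Free entries carry labels in lavaan-like
notation (``target~source`` for paths, ``a~~b`` for (co)variances,
``latent=~indicator`` for loadings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SemSpec",
    "build_spec",
    "implied_covariance",
    "saturated_spec",
    "independence_spec",
]


@dataclass(frozen=True)
class SemSpec:
    """A validated RAM-form model pattern.

    ``a_free``/``s_free`` list ``(row, col, param_index)`` triples into the
    pattern matrices (``s_free`` stores the lower triangle; symmetry is
    applied when materializing).  ``indicators`` are observed variables
    whose only structural role is measuring a latent; the remaining
    variables form the structural part used for effect decomposition.
    """

    observed: tuple[str, ...]
    latents: tuple[str, ...]
    a_fixed: np.ndarray
    s_fixed: np.ndarray
    a_free: tuple[tuple[int, int, int], ...]
    s_free: tuple[tuple[int, int, int], ...]
    parameter_labels: tuple[str, ...]
    indicators: frozenset[str] = field(default_factory=frozenset)

    @property
    def variables(self) -> tuple[str, ...]:
        return self.observed + self.latents

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_free(self) -> int:
        return len(self.parameter_labels)

    @property
    def df(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 - self.n_free

    def index(self, name: str) -> int:
        return self.variables.index(name)

    def matrices(self, theta: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Materialize (A, S) at a parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(
                f"theta has length {theta.size}, model has {self.n_free} free parameters"
            )
        a = self.a_fixed.copy()
        s = self.s_fixed.copy()
        for i, j, k in self.a_free:
            a[i, j] = theta[k]
        for i, j, k in self.s_free:
            s[i, j] = theta[k]
            s[j, i] = theta[k]
        return a, s

    def validate(self) -> None:
        m = len(self.variables)
        if self.a_fixed.shape != (m, m) or self.s_fixed.shape != (m, m):
            raise ValueError("pattern matrices do not match the variable list")
        if np.diag(self.a_fixed).any() or any(i == j for i, j, _ in self.a_free):
            raise ValueError("A must have a zero diagonal")
        if not np.allclose(self.s_fixed, self.s_fixed.T):
            raise ValueError("fixed part of S must be symmetric")
        seen = set()
        for lab in self.parameter_labels:
            if lab in seen:
                raise ValueError(f"duplicate parameter label {lab!r}")
            seen.add(lab)
        used = {k for _, _, k in self.a_free} | {k for _, _, k in self.s_free}
        if used != set(range(self.n_free)):
            raise ValueError("every free label must appear exactly once in a pattern")
        if self.df < 0:
            raise ValueError(
                f"model has negative degrees of freedom ({self.df}): under-identified"
            )
        # the directed part must be recursive (acyclic)
        edges: dict[int, set[int]] = {i: set() for i in range(m)}
        for i, j in zip(*np.nonzero(self.a_fixed)):
            edges[int(i)].add(int(j))  # i depends on j
        for i, j, _ in self.a_free:
            edges[i].add(j)
        try:
            tuple(TopologicalSorter(edges).static_order())
        except CycleError as exc:
            raise ValueError("directed paths contain a cycle") from exc

    # -- structural part ------------------------------------------------
    def structural_variables(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if v not in self.indicators)

    def structural_matrix(self, theta: Sequence[float]) -> tuple[np.ndarray, tuple[str, ...]]:
        """The B matrix restricted to non-indicator variables."""
        a, _ = self.matrices(theta)
        names = self.structural_variables()
        idx = [self.index(v) for v in names]
        return a[np.ix_(idx, idx)], names


def implied_covariance(spec: SemSpec, theta: Sequence[float]) -> np.ndarray:
    """Model-implied covariance of the observed variables.

    ``Sigma = F (I-A)^-1 S (I-A)^-T F^T``; symmetric by construction.
    Raises when ``I - A`` is singular.
    """
    v = implied_covariance_full(spec, theta)
    p = spec.n_observed
    return v[:p, :p]


def implied_covariance_full(spec: SemSpec, theta: Sequence[float]) -> np.ndarray:
    """Implied covariance of all variables (observed and latent)."""
    a, s = spec.matrices(theta)
    m = a.shape[0]
    try:
        minv = np.linalg.inv(np.eye(m) - a)
    except np.linalg.LinAlgError as exc:
        raise ValueError("I - A is singular") from exc
    v = minv @ s @ minv.T
    return (v + v.T) / 2.0


def build_spec(
    measurement: Mapping[str, Sequence[str]],
    structural: Iterable[tuple[str, str]],
    covariances: Iterable[tuple[str, str]] = (),
    fixed_paths: Mapping[tuple[str, str], float] | None = None,
    identification: str = "first_loading_fixed_1",
    observed_order: Sequence[str] | None = None,
) -> SemSpec:
    """Assemble and validate a RAM specification.

    Parameters
    ----------
    measurement
        latent name -> ordered indicator list.  Each latent needs at least
        one indicator.
    structural
        free directed paths ``(source, target)`` among structural
        variables (observed or latent).
    covariances
        free covariance pairs (typically among exogenous stressors).
        Exogenous variances and endogenous residual variances are free
        automatically.
    fixed_paths
        optional ``(source, target) -> value`` entries fixed rather than
        estimated.
    identification
        ``first_loading_fixed_1`` fixes each latent's first loading to 1;
        ``latent_variance_fixed_1`` frees all loadings and fixes the
        latent (residual) variance to 1.
    """
    structural = list(structural)
    fixed_paths = dict(fixed_paths or {})
    latents = tuple(measurement)
    indicator_set: list[str] = []
    for lat, inds in measurement.items():
        if len(inds) < 1:
            raise ValueError(f"latent {lat!r} has no indicators")
        indicator_set.extend(inds)
    structural_vars: list[str] = []
    for src, dst in structural + list(fixed_paths):
        for v in (src, dst):
            if v not in structural_vars and v not in latents and v not in indicator_set:
                structural_vars.append(v)
    observed = list(observed_order) if observed_order is not None else (
        structural_vars + [i for i in indicator_set if i not in structural_vars]
    )
    for ind in indicator_set:
        if ind not in observed:
            raise ValueError(f"indicator {ind!r} missing from observed order")
    variables = tuple(observed) + latents
    m = len(variables)
    pos = {v: i for i, v in enumerate(variables)}
    if len(pos) != m:
        raise ValueError("duplicate variable names")

    a_fixed = np.zeros((m, m))
    s_fixed = np.zeros((m, m))
    a_free: list[tuple[int, int, int]] = []
    s_free: list[tuple[int, int, int]] = []
    labels: list[str] = []

    def add(label: str) -> int:
        labels.append(label)
        return len(labels) - 1

    # measurement part
    for lat, inds in measurement.items():
        for j, ind in enumerate(inds):
            if identification == "first_loading_fixed_1" and j == 0:
                a_fixed[pos[ind], pos[lat]] = 1.0
            else:
                a_free.append((pos[ind], pos[lat], add(f"{lat}=~{ind}")))
    # structural part
    for src, dst in structural:
        a_free.append((pos[dst], pos[src], add(f"{dst}~{src}")))
    for (src, dst), val in fixed_paths.items():
        a_fixed[pos[dst], pos[src]] = val

    has_incoming = {dst for _, dst in structural} | {dst for _, dst in fixed_paths}
    has_incoming |= set(indicator_set)
    # variances: every variable gets a free (residual) variance unless the
    # identification rule fixes the latent variance
    for v in variables:
        if (
            identification == "latent_variance_fixed_1"
            and v in latents
        ):
            s_fixed[pos[v], pos[v]] = 1.0
        else:
            s_free.append((pos[v], pos[v], add(f"{v}~~{v}")))
    for x, y in covariances:
        i, j = pos[x], pos[y]
        if i == j:
            raise ValueError("use variances, not self-covariances")
        if x in has_incoming or y in has_incoming:
            raise ValueError(f"free covariance {x}~~{y} involves an endogenous variable")
        s_free.append((max(i, j), min(i, j), add(f"{x}~~{y}")))

    spec = SemSpec(
        observed=tuple(observed),
        latents=latents,
        a_fixed=a_fixed,
        s_fixed=s_fixed,
        a_free=tuple(a_free),
        s_free=tuple(s_free),
        parameter_labels=tuple(labels),
        indicators=frozenset(indicator_set),
    )
    spec.validate()
    return spec


def saturated_spec(observed: Sequence[str]) -> SemSpec:
    """All variances and covariances free, no paths (df = 0)."""
    observed = tuple(observed)
    m = len(observed)
    labels: list[str] = []
    s_free: list[tuple[int, int, int]] = []
    for i in range(m):
        for j in range(i + 1):
            labels.append(f"{observed[i]}~~{observed[j]}")
            s_free.append((i, j, len(labels) - 1))
    spec = SemSpec(
        observed=observed,
        latents=(),
        a_fixed=np.zeros((m, m)),
        s_fixed=np.zeros((m, m)),
        a_free=(),
        s_free=tuple(s_free),
        parameter_labels=tuple(labels),
    )
    spec.validate()
    return spec


def independence_spec(observed: Sequence[str]) -> SemSpec:
    """The baseline model: variances free, all covariances fixed to zero."""
    observed = tuple(observed)
    m = len(observed)
    labels = [f"{v}~~{v}" for v in observed]
    s_free = tuple((i, i, i) for i in range(m))
    spec = SemSpec(
        observed=observed,
        latents=(),
        a_fixed=np.zeros((m, m)),
        s_fixed=np.zeros((m, m)),
        a_free=(),
        s_free=s_free,
        parameter_labels=tuple(labels),
    )
    spec.validate()
    return spec
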