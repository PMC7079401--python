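"""The default stress-process model for antenatal depression.

Variables (all per analysis subject):

* stressors (exogenous, binary coded 0/1): adequate food access
  (``food_adequate``), unplanned pregnancy (``unplanned``), fear of giving
  birth (``fear_birth``), history of a common mental disorder
  (``history_cmd``);
* mediators (observed ordinal scores treated as continuous): marital
  agreement (1-4), partner support (1-5), social support (OSSS-3 total,
  3-14);
* outcome: a latent depression factor measured by the three EPDS parcels
  ``epds_p1``/``epds_p2``/``epds_p3``.

The mediators form a chain (marital agreement -> partner support ->
social support); stressors feed selected mediators and all predictors
feed the latent outcome directly, so every stressor can act both directly
and through the psychosocial resources.  Exogenous stressors are freely
correlated.  The exact mediation topology is not uniquely pinned down by
the published effect table; this default reproduces its decomposition
pattern (social support purely direct; marital agreement and partner
support with indirect components) and alternative topologies can be
passed to :func:`stressproc.sem.build_spec` directly.
"""

from __future__ import annotations

import numpy as np

from .sem import SemSpec, build_spec

__all__ = [
    "STRESSORS",
    "MEDIATORS",
    "OUTCOME",
    "PARCELS",
    "STRUCTURAL_EDGES",
    "TABLE4_TARGETS",
    "default_sem_spec",
    "structural_b_matrix",
]

STRESSORS: tuple[str, ...] = ("food_adequate", "unplanned", "fear_birth", "history_cmd")
MEDIATORS: tuple[str, ...] = ("marital_agreement", "partner_support", "social_support")
OUTCOME = "depression"
PARCELS: tuple[str, ...] = ("epds_p1", "epds_p2", "epds_p3")

#: Directed edges of the structural part, excluding the direct paths into
#: the outcome (every stressor and mediator also points at ``depression``).
STRESSOR_MEDIATOR_EDGES: tuple[tuple[str, str], ...] = (
    ("unplanned", "marital_agreement"),
    ("food_adequate", "marital_agreement"),
    ("food_adequate", "social_support"),
    ("fear_birth", "social_support"),
    ("history_cmd", "social_support"),
    ("marital_agreement", "partner_support"),
    ("partner_support", "social_support"),
)

STRUCTURAL_EDGES: tuple[tuple[str, str], ...] = STRESSOR_MEDIATOR_EDGES + tuple(
    (v, OUTCOME) for v in STRESSORS + MEDIATORS
)

#: Published standardized (direct, indirect) effects on the depression
#: score, per predictor.
TABLE4_TARGETS: dict[str, tuple[float, float]] = {
    "marital_agreement": (-0.20, -0.08),
    "partner_support": (-0.14, -0.04),
    "social_support": (-0.21, 0.0),
    "food_adequate": (-0.11, -0.04),
    "unplanned": (0.15, 0.11),
    "fear_birth": (0.29, 0.01),
    "history_cmd": (0.18, -0.01),
}


def default_sem_spec() -> SemSpec:
    """The packaged stress-process model as a validated RAM spec."""
    covariances = [
        (a, b)
        for i, a in enumerate(STRESSORS)
        for b in STRESSORS[i + 1 :]
    ]
    return build_spec(
        measurement={OUTCOME: list(PARCELS)},
        structural=list(STRUCTURAL_EDGES),
        covariances=covariances,
        observed_order=list(STRESSORS + MEDIATORS + PARCELS),
    )


def structural_b_matrix(
    paths: dict[tuple[str, str], float],
    variables: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Assemble the structural coefficient matrix B (entry [target, source])
    from a path -> value map.

    ``variables`` defaults to the packaged model's variable set; any other
    topology may pass its own ordered name list.
    """
    if variables is None:
        default = STRESSORS + MEDIATORS + (OUTCOME,)
        used = {v for edge in paths for v in edge}
        if used <= set(default):
            variables = default
        else:  # generic topology: sources in order of appearance, then rest
            seen: list[str] = []
            for src, dst in paths:
                for v in (src, dst):
                    if v not in seen:
                        seen.append(v)
            variables = tuple(seen)
    names = variables
    pos = {v: i for i, v in enumerate(names)}
    b = np.zeros((len(names), len(names)))
    for (src, dst), val in paths.items():
        b[pos[dst], pos[src]] = val
    return b, names
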