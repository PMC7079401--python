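"""Item parceling for the EPDS measurement model.

The measurement model for the depression latent uses three parcels of EPDS
items rather than the ten raw items.  The study's fixed assignment is
P1 = {1, 4, 9}, P2 = {6, 7, 8}, P3 = {2, 3, 5, 10} (1-based item numbers);
a seeded uniformly-random partition with near-equal parcel sizes is also
provided for re-randomization checks.  Parcel scores are item sums, so the
parcel scores of a subject always add up to the EPDS total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ParcelScheme", "PAPER_ASSIGNMENT", "make_parcels", "parcel_scores"]

#: The study's fixed parcel assignment (1-based EPDS item numbers).
PAPER_ASSIGNMENT: dict[int, tuple[int, ...]] = {
    1: (1, 4, 9),
    2: (6, 7, 8),
    3: (2, 3, 5, 10),
}


@dataclass(frozen=True)
class ParcelScheme:
    """A partition of 1-based item indices into parcels.

    ``assignment`` maps item index -> parcel index (1-based).
    """

    assignment: Mapping[int, int]
    n_items: int
    k: int
    scheme: str
    seed: int | None = None

    def __post_init__(self) -> None:
        items = sorted(self.assignment)
        if items != list(range(1, self.n_items + 1)):
            raise ValueError("assignment must cover items 1..n exactly once")
        parcels = set(self.assignment.values())
        if parcels != set(range(1, self.k + 1)):
            raise ValueError("parcels must be 1..k and all non-empty")

    def members(self, parcel: int) -> tuple[int, ...]:
        return tuple(i for i, p in sorted(self.assignment.items()) if p == parcel)

    def to_dict(self) -> dict[str, list[int]]:
        """JSON-friendly form, e.g. ``{"P1": [1, 4, 9], ...}``."""
        return {f"P{p}": list(self.members(p)) for p in range(1, self.k + 1)}


def make_parcels(
    n_items: int, k: int, scheme: str = "paper", seed: int | None = None
) -> ParcelScheme:
    """Build a parcel scheme.

    ``scheme="paper"`` returns the study's fixed 10-item/3-parcel
    assignment and rejects any other (n_items, k).  ``scheme="random"``
    draws a uniformly random partition with sizes as equal as possible
    (e.g. 3, 3, 4 for ten items in three parcels), reproducible from
    ``seed``; the draw uses integer arithmetic on a seeded PCG64 stream.
    """
    if not 1 <= k <= n_items:
        raise ValueError("need 1 <= k <= n_items")
    if scheme == "paper":
        if (n_items, k) != (10, 3):
            raise ValueError("the fixed assignment is defined for 10 items in 3 parcels")
        assignment = {
            item: parcel for parcel, items in PAPER_ASSIGNMENT.items() for item in items
        }
        return ParcelScheme(assignment, n_items, k, "paper")
    if scheme != "random":
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items) + 1
    base, extra = divmod(n_items, k)
    sizes = [base + (1 if j < extra else 0) for j in range(k)]
    assignment: dict[int, int] = {}
    pos = 0
    for parcel, size in enumerate(sizes, start=1):
        for item in order[pos : pos + size]:
            assignment[int(item)] = parcel
        pos += size
    return ParcelScheme(assignment, n_items, k, "random", seed)


def parcel_scores(epds_items: Sequence[int], scheme: ParcelScheme) -> np.ndarray:
    """Sum direction-coded item responses within each parcel.

    The returned vector has one entry per parcel and sums to the EPDS
    total.  Also accepts a 2-d (subjects x items) array, returning a
    (subjects x k) array.
    """
    x = np.asarray(epds_items, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != scheme.n_items:
        raise ValueError(
            f"scheme covers {scheme.n_items} items but got {x.shape[1]} responses"
        )
    out = np.zeros((x.shape[0], scheme.k))
    for item, parcel in scheme.assignment.items():
        out[:, parcel - 1] += x[:, item - 1]
    return out[0] if squeeze else out
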