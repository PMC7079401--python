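"""Cohort CSV reading/writing, codings, and the model-file format.

The packaged data dictionary (:data:`DATA_DICTIONARY`) documents every
ordinal coding the pipeline expects.  The reader accepts a column-mapping
config (file column name -> canonical role) and can apply the standard
EPDS direction key to raw response-option indices
(:data:`stressproc.scales.EPDS_REVERSE_CODED_ITEMS`), keeping the scorers
pure.

Model files are small YAML documents::

    latents:
      depression: [epds_p1, epds_p2, epds_p3]
    paths:
      - fear_birth -> depression
      - marital_agreement -> partner_support
    covariances:
      - fear_birth ~~ history_cmd
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .scales import EPDS_REVERSE_CODED_ITEMS
from .sem import SemSpec, build_spec

__all__ = ["DATA_DICTIONARY", "read_cohort", "load_model_yaml", "model_to_yaml"]

EPDS_COLUMNS = tuple(f"epds_{i}" for i in range(1, 11))
OSSS_COLUMNS = ("osss_1", "osss_2", "osss_3")
PCI_COLUMNS = tuple(f"pci_{i}" for i in range(1, 5))

#: canonical column -> coding description
DATA_DICTIONARY: dict[str, str] = {
    **{c: "EPDS item, 0-3 coded toward distress" for c in EPDS_COLUMNS},
    "osss_1": "OSSS-3 'people to count on', 1-4",
    "osss_2": "OSSS-3 'concern and interest', 1-5",
    "osss_3": "OSSS-3 'practical help', 1-5",
    **{c: "PCI-4 coping item, 0 never .. 3 most of the time" for c in PCI_COLUMNS},
    "partner_support": "1 never .. 5 always",
    "marital_agreement": "1 never .. 4 most of the time",
    "food_access_difficulty": "1 = difficulty accessing food, last 3 months",
    "pregnancy_intention": "planned | untimed | unintended",
    "fear_of_birth": "1 = fears giving birth",
    "history_cmd": "1 = history of a common mental disorder",
    "gestational_weeks": "integer weeks, 13-42",
    "muac_cm": "mid-upper-arm circumference, cm",
    "cluster_id": "kebele identifier",
    "subject_id": "opaque identifier",
}

REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "cluster_id",
    *EPDS_COLUMNS,
    *OSSS_COLUMNS,
    "partner_support",
    "marital_agreement",
    "food_access_difficulty",
    "pregnancy_intention",
    "fear_of_birth",
    "history_cmd",
)


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    epds_coding: str = "coded",
) -> pd.DataFrame:
    """Read a cohort CSV into the canonical column layout.

    ``column_map`` maps file column names to canonical roles.
    ``epds_coding="raw"`` treats EPDS columns as 0-3 response-option
    indices in presentation order and applies the published direction key
    (items 3, 5-10 reverse-coded); the default expects items already coded
    toward distress.  Records with missing required values are rejected
    (complete-case analysis, no imputation).
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns {missing}")
    if frame[list(REQUIRED_COLUMNS)].isna().any().any():
        bad = int(frame[list(REQUIRED_COLUMNS)].isna().any(axis=1).sum())
        raise ValueError(f"{bad} records have missing required values (no imputation)")
    if epds_coding == "raw":
        for i in EPDS_REVERSE_CODED_ITEMS:
            frame[f"epds_{i}"] = 3 - frame[f"epds_{i}"]
    elif epds_coding != "coded":
        raise ValueError("epds_coding must be 'coded' or 'raw'")
    return frame


def load_model_yaml(path: str | Path) -> SemSpec:
    """Build a validated SemSpec from a YAML model file."""
    doc = yaml.safe_load(Path(path).read_text())
    measurement = {str(k): [str(v) for v in vs] for k, vs in (doc.get("latents") or {}).items()}

    def parse_edges(entries, sep):
        out = []
        for entry in entries or []:
            parts = [p.strip() for p in str(entry).split(sep)]
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"cannot parse model entry {entry!r}")
            out.append((parts[0], parts[1]))
        return out

    fixed = {}
    for entry, value in (doc.get("fix") or {}).items():
        (src, dst), = [parse_edges([entry], "->")]
        fixed[(src, dst)] = float(value)
    return build_spec(
        measurement=measurement,
        structural=parse_edges(doc.get("paths"), "->"),
        covariances=parse_edges(doc.get("covariances"), "~~"),
        fixed_paths=fixed or None,
        identification=doc.get("identification", "first_loading_fixed_1"),
        observed_order=doc.get("observed_order"),
    )


def model_to_yaml(spec: SemSpec) -> str:
    """Serialize a SemSpec back to the YAML model format (free entries)."""
    doc: dict = {"latents": {}, "paths": [], "covariances": []}
    names = spec.variables
    for lat in spec.latents:
        li = spec.index(lat)
        inds = [names[i] for i in range(spec.n_observed) if spec.a_fixed[i, li] != 0]
        inds += [names[i] for i, j, _ in spec.a_free
                 if j == li and names[i] in spec.indicators]
        doc["latents"][lat] = list(dict.fromkeys(inds))
    for i, j, k in spec.a_free:
        if "=~" not in spec.parameter_labels[k]:
            doc["paths"].append(f"{names[j]} -> {names[i]}")
    for i, j, k in spec.s_free:
        if i != j:
            doc["covariances"].append(f"{names[j]} ~~ {names[i]}")
    return yaml.safe_dump(doc, sort_keys=False)
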