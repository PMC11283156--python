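"""YAML/JSON experiment configuration.

A config document mirrors the summary-table structure of the source data:

.. code-block:: yaml

    cohort:
      n_mild: 220
      n_severe: 188
      n_features_total: 40
      missing_rate: 0.0
      male_counts: {mild: 188, severe: 157}
      features:
        - name: age
          mild_ci: [77.6, 80.0]
          severe_ci: [80.2, 82.8]
          bounds: [18, 110]
    fl:
      n_clients: 3
      rounds: 350
      split: [7, 3]
      train: {eta: 0.001, epochs: 5, batch_size: 10}
    samples_per_client: 136
    axis: none
    axis_values: []

Omitted sections fall back to the published defaults.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .cohort import MILD, SEVERE, CohortConfig, FeatureSpec
from .experiments import ExperimentSpec
from .federation import FLConfig
from .network import TrainConfig


def _cohort_from_doc(doc: dict) -> CohortConfig:
    kwargs = dict(doc)
    if "features" in kwargs:
        kwargs["features"] = tuple(
            FeatureSpec(
                name=f["name"],
                mild_ci=tuple(f["mild_ci"]),
                severe_ci=tuple(f["severe_ci"]),
                bounds=tuple(f["bounds"]) if f.get("bounds") else None,
            )
            for f in kwargs["features"]
        )
    if "male_counts" in kwargs:
        mc = kwargs["male_counts"]
        kwargs["male_counts"] = {MILD: int(mc["mild"]), SEVERE: int(mc["severe"])}
    return CohortConfig(**kwargs)


def _fl_from_doc(doc: dict) -> FLConfig:
    kwargs = dict(doc)
    if "train" in kwargs:
        kwargs["train"] = TrainConfig(**kwargs["train"])
    if "split" in kwargs:
        kwargs["split"] = tuple(float(x) for x in kwargs["split"])
    if "hidden" in kwargs:
        kwargs["hidden"] = tuple(int(h) for h in kwargs["hidden"])
    return FLConfig(**kwargs)


def load_spec(path: str | Path | None) -> ExperimentSpec:
    """Build an :class:`ExperimentSpec` from a YAML/JSON file (or defaults)."""
    doc = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    cohort = _cohort_from_doc(doc.get("cohort", {}))
    fl = _fl_from_doc(doc.get("fl", {}))
    axis_values = doc.get("axis_values", [])
    axis = doc.get("axis", "none")
    if axis == "split":
        axis_values = [tuple(v) for v in axis_values]
    return ExperimentSpec(
        cohort=cohort,
        fl=fl,
        samples_per_client=doc.get("samples_per_client"),
        missing_threshold=doc.get("missing_threshold", 0.10),
        axis=axis,
        axis_values=tuple(axis_values),
        repeats=doc.get("repeats", 1),
    )


def spec_to_doc(spec: ExperimentSpec) -> dict:
    """A JSON-serialisable document for manifests and audit logs."""
    return asdict(spec)
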