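"""Versioned JSON persistence for fitted models.

A model document bundles everything prediction needs: kernel specs and
weights, the γ vector, labels and encoded training matrix, bias, Platt
calibration, operating threshold, and the preprocessor (schema plus frozen
z-scoring statistics).  A save→load round-trip reproduces decision scores
bit-for-bit: floats survive JSON via shortest-round-trip repr.
"""

from __future__ import annotations

import json

import numpy as np

from .cohort import ColumnSpec, Preprocessor
from .easymkl import MkModel
from .kernels import KernelSpec

FORMAT_VERSION = 1


class ModelIOError(RuntimeError):
    """Unreadable, corrupted, or version-incompatible model file."""


def save_model(model: MkModel, preprocessor: Preprocessor, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "model": {
            "X_train": model.X_train.tolist(),
            "y_train": model.y_train.tolist(),
            "specs": [s.to_dict() for s in model.specs],
            "eta": model.eta.tolist(),
            "gamma": model.gamma.tolist(),
            "bias": model.bias,
            "kernel_scales": model.kernel_scales.tolist(),
            "platt_a": model.platt_a,
            "platt_b": model.platt_b,
            "operating_threshold": model.operating_threshold,
            "phi": model.phi,
        },
        "preprocessor": {
            "schema": [
                {"name": c.name, "kind": c.kind, "categories": list(c.categories)}
                for c in preprocessor.schema
            ],
            "means": preprocessor.means,
            "sds": preprocessor.sds,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> tuple[MkModel, Preprocessor]:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelIOError(f"corrupted model file {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelIOError(
            f"model file version {version!r} does not match supported version {FORMAT_VERSION}"
        )
    try:
        m = doc["model"]
        p = doc["preprocessor"]
        model = MkModel(
            X_train=np.asarray(m["X_train"], dtype=float),
            y_train=np.asarray(m["y_train"], dtype=int),
            specs=[KernelSpec.from_dict(s) for s in m["specs"]],
            eta=np.asarray(m["eta"], dtype=float),
            gamma=np.asarray(m["gamma"], dtype=float),
            bias=float(m["bias"]),
            kernel_scales=np.asarray(m["kernel_scales"], dtype=float),
            platt_a=m["platt_a"],
            platt_b=m["platt_b"],
            operating_threshold=float(m["operating_threshold"]),
            phi=float(m["phi"]),
        )
        schema = tuple(
            ColumnSpec(c["name"], c["kind"], tuple(c["categories"])) for c in p["schema"]
        )
        pre = Preprocessor(schema=schema, means=dict(p["means"]), sds=dict(p["sds"]), fitted=True)
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"malformed model document in {path}: {exc}") from exc
    return model, pre
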