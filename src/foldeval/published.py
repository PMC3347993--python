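"""Published reference results of a multi-class RNA structure benchmark.

The packaged table holds per-class mean F-measures of six
predictor/parameter-set combinations on the eight-class MT dataset, the
dataset's within-class mean normalized structure similarities, and 95%
bootstrap percentile confidence intervals on the larger MA and S-Full
datasets.  It serves as input for recomputing the benchmark's derived
quantities — the three class-averaging schemes and confidence-interval
width comparisons — with this package's accuracy layer.
"""

from __future__ import annotations

import json
from importlib import resources

from .accuracy_metrics import ClassAccuracy

__all__ = ["load_published_benchmark", "published_class_accuracies"]


def load_published_benchmark() -> dict:
    """The packaged published-benchmark table, as a plain dict."""
    ref = resources.files("foldeval.data").joinpath("published_benchmark.json")
    return json.loads(ref.read_text())


def published_class_accuracies(column: str, similarity_source: str = "mt"):
    """Per-class accuracy objects for one predictor column of the MT table.

    Each class carries its printed size, its mean normalized similarity and
    its printed per-class mean F (expanded to a constant per-record value,
    which leaves all three averaging schemes unchanged).
    """
    doc = load_published_benchmark()
    mt = doc["mt"]
    values = mt["f_per_class"][column]
    return [
        ClassAccuracy(label=lab, similarity=sim, values=(val,) * size)
        for lab, size, sim, val in zip(
            doc["classes"], mt["class_sizes"], mt["similarity"], values
        )
    ]
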