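"""Structured analysis reports.

An :class:`AnalysisReport` records what was run (analysis kind, input
digests, configuration echo), the fitted parameters with their
uncertainties, and any derived quantities (Ki, P_i table, survival
curve, processivity length, fold stimulation). Reports serialize to
JSON losslessly: ``AnalysisReport.from_json(r.to_json()) == r``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from . import __version__

__all__ = ["AnalysisReport"]


def _jsonify(obj):
    """Coerce numpy scalars/arrays into plain JSON types."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class AnalysisReport:
    """Serializable record of one analysis run."""

    kind: str
    inputs: dict = field(default_factory=dict)       # name -> sha256
    parameters: dict = field(default_factory=dict)   # fitted, with stderr
    derived: dict = field(default_factory=dict)      # downstream quantities
    warnings: list = field(default_factory=list)
    config: dict = field(default_factory=dict)       # config/seed echo
    version: str = __version__

    def to_dict(self) -> dict:
        return _jsonify(asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(**d)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnalysisReport):
            return NotImplemented
        return self.to_dict() == other.to_dict()
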