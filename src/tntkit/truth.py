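"""Ground-truth sidecar records for synthetic data.

Every generator in :mod:`tntkit.simulate` returns its output together with
exactly one :class:`TruthRecord` holding the seed and every quantity a
downstream recovery test needs (true decay length, scheduled peak times,
true differential protein set, ...).  Records serialize to a JSON sidecar
``<output>.truth.json`` next to the data file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


def _jsonable(obj: Any) -> Any:
    """Coerce numpy scalars/arrays and tuples into plain JSON types."""
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)


@dataclass
class TruthRecord:
    """Provenance + ground truth for one synthetic dataset."""

    generator: str
    seed: int
    parameters: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "generator": self.generator,
            "seed": int(self.seed),
            "parameters": _jsonable(self.parameters),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            generator=payload["generator"],
            seed=payload["seed"],
            parameters=payload["parameters"],
        )

    def sidecar_path(self, output_path: str | Path) -> Path:
        return Path(str(output_path) + ".truth.json")
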