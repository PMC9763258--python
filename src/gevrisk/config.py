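"""Unified run configuration.

Every free parameter of the pipeline lives here with its default, so a run
can be reproduced from the serialized config alone.  Reports embed
``config_hash`` for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Literal

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class DbscanConfig:
    """DBSCAN parameters for red-color-sign clustering.

    ``eps_mode='formula'`` derives the neighbourhood radius from the frame
    size as sqrt(w*h/6.5); ``'fixed'`` uses ``eps_value`` pixels.
    """

    min_pts: int = 1
    eps_mode: Literal["formula", "fixed"] = "formula"
    eps_value: float | None = None


@dataclass(frozen=True)
class RCThresholds:
    """Numeric operationalization of the qualitative RC1/RC2/RC3 criteria.

    RC1 ("small in number and localized"): at most ``n1`` clusters spanning
    at most ``a1`` degrees around the lumen.  RC3 ("large in number and
    circumferential"): at least ``n3`` clusters or a span of at least ``a3``
    degrees.  RC2 is everything in between.
    """

    n1: int = 2
    a1: float = 90.0
    n3: int = 6
    a3: float = 270.0


@dataclass(frozen=True)
class GradeThresholds:
    """Width/shape cut points for the geometric EV grade stand-in.

    w12 (mm) separates small-caliber grade-1 from moderately enlarged
    grade-2 varices; w23 (mm) marks markedly enlarged grade-3; cv bounds the
    width variation tolerated for a "straight" grade-1 varix; nodular
    varices (>= nodularity_3 local bulges) are grade 3.
    """

    w12: float = 3.0
    w23: float = 5.0
    cv: float = 0.15
    nodularity_3: int = 2
    gv_big_mm: float = 5.0


@dataclass(frozen=True)
class SmoothingConfig:
    """Temporal majority smoothing: a label wins a window of ``window``
    consecutive qualified frames when it occurs at least ``quorum`` times;
    otherwise the highest-severity modal label is emitted."""

    window: int = 5
    quorum: int = 3
    tie_break: Literal["highest_severity"] = "highest_severity"


@dataclass(frozen=True)
class RunConfig:
    cutoff_varix: float = 0.4
    cutoff_rc: float = 0.5
    dbscan: DbscanConfig = field(default_factory=DbscanConfig)
    rc_thresholds: RCThresholds = field(default_factory=RCThresholds)
    grade_thresholds: GradeThresholds = field(default_factory=GradeThresholds)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    aggregation_floor: float = 0.05
    risk_rule: Literal["intro", "methods"] = "intro"
    coverage_threshold: float = 0.5
    ci_method: Literal["agresti-coull", "clopper-pearson"] = "agresti-coull"
    min_instance_area: int = 10
    min_rc_area: int = 10
    connectivity: int = 8
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        d["dbscan"] = DbscanConfig(**d.get("dbscan", {}))
        d["rc_thresholds"] = RCThresholds(**d.get("rc_thresholds", {}))
        d["grade_thresholds"] = GradeThresholds(**d.get("grade_thresholds", {}))
        d["smoothing"] = SmoothingConfig(**d.get("smoothing", {}))
        return cls(**d)


DEFAULT_CONFIG = RunConfig()
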