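"""Subject profiles: discretization, polarity handling and departure scores.

Instrument totals (e.g. mood-survey or frontal-systems subscale scores) are
range-normalized onto the four qualitative levels used by the logic engine.
Constructs measured as *function* (higher = better) are reversed at ingest so
that inside the model every behavioral node is expressed as severity of the
corresponding dysfunction.  Model fit is quantified by the Manhattan distance
between predicted and observed levels, expressed as a fraction of the maximum
possible misalignment (3 per compared construct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .logic_engine import LEVELS, MAX_LEVEL
from .network_io import Network


class ProfileError(ValueError):
    """Raised for malformed profiles or out-of-range scores."""


@dataclass
class SubjectProfile:
    """Partial observation of one subject: behavioral construct -> level 0-3."""

    subject_id: str
    observed: dict[str, int]

    def __post_init__(self) -> None:
        for k, v in self.observed.items():
            if v not in LEVELS:
                raise ProfileError(
                    f"subject {self.subject_id}: level {v} for {k!r} outside 0..3"
                )

    def restrict(self, nodes: list[str]) -> "SubjectProfile":
        return SubjectProfile(self.subject_id,
                              {k: v for k, v in self.observed.items() if k in nodes})


@dataclass
class Departure:
    """Manhattan misalignment between a prediction and an observation.

    ``absolute`` sums |predicted - observed| over the compared nodes;
    ``normalized`` divides by the maximum possible (3 per node, times the
    number of subjects when aggregated).
    """

    absolute: int
    n_compared: int
    n_subjects: int = 1
    nodes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def normalized(self) -> float:
        denom = MAX_LEVEL * self.n_compared * self.n_subjects
        return self.absolute / denom if denom else 0.0


def control_profile(net: Network) -> dict[str, int]:
    """The idealized control: minimal severity and optimal function.

    Severity-polarity behavioral nodes sit at 0, function-polarity nodes at 3.
    """
    targets = {}
    for nid in net.behavioral:
        pol = net.nodes[nid].polarity
        targets[nid] = MAX_LEVEL if pol == "function" else 0
    if not targets:
        raise ProfileError("network has no behavioral nodes")
    return targets


def discretize_score(raw: float, scale_min: float, scale_max: float) -> int:
    """Range-normalize a raw instrument total into four equal-width bins.

    level = min(3, floor(4 * (raw - min) / (max - min))); the scale maximum
    maps to 3 (top bin closed).
    """
    if scale_max <= scale_min:
        raise ProfileError("scale_max must exceed scale_min")
    if not (scale_min <= raw <= scale_max):
        raise ProfileError(
            f"score {raw} outside the instrument range [{scale_min}, {scale_max}]"
        )
    frac = (raw - scale_min) / (scale_max - scale_min)
    return min(MAX_LEVEL, int(4 * frac))


def reverse_function_scale(level: int) -> int:
    """Map a function level to the severity of the opposite construct (3 - l).

    Used e.g. to express low executive function as high executive dysfunction.
    """
    if level not in LEVELS:
        raise ProfileError(f"level {level} outside 0..3")
    return MAX_LEVEL - level


def manhattan_departure(predicted: dict[str, int],
                        observed: SubjectProfile) -> Departure:
    """Departure of a predicted full state from one subject's observations.

    Comparison is restricted to the observed nodes; every observed node must
    be present in the prediction.
    """
    total = 0
    for nid, lv in observed.observed.items():
        if nid not in predicted:
            raise ProfileError(f"predicted state lacks observed node {nid!r}")
        total += abs(int(predicted[nid]) - lv)
    return Departure(absolute=total, n_compared=len(observed.observed),
                     nodes=tuple(sorted(observed.observed)))


def aggregate_departure(per_subject: list[Departure]) -> Departure:
    """Pool departures across subjects sharing one construct set."""
    if not per_subject:
        raise ProfileError("no departures to aggregate")
    nodes = per_subject[0].nodes
    for d in per_subject[1:]:
        if d.nodes != nodes:
            raise ProfileError("departures cover heterogeneous node sets")
    return Departure(
        absolute=sum(d.absolute for d in per_subject),
        n_compared=per_subject[0].n_compared,
        n_subjects=sum(d.n_subjects for d in per_subject),
        nodes=nodes,
    )


# -- file formats ----------------------------------------------------------

def read_profiles(path: str) -> list[SubjectProfile]:
    """Profiles CSV: rows = subjects (index column), columns = constructs,
    integer cells 0-3."""
    df = pd.read_csv(path, index_col=0)
    out = []
    for sid, row in df.iterrows():
        out.append(SubjectProfile(str(sid), {c: int(row[c]) for c in df.columns}))
    return out


def write_profiles(profiles: list[SubjectProfile], path: str) -> str:
    cols = sorted(profiles[0].observed)
    df = pd.DataFrame([[p.observed[c] for c in cols] for p in profiles],
                      index=pd.Index([p.subject_id for p in profiles],
                                     name="subject"),
                      columns=cols)
    df.to_csv(path)
    return path


def load_raw_scores(path: str, scales_yaml: str) -> list[SubjectProfile]:
    """Discretize raw instrument totals into level profiles.

    The YAML config maps construct -> {scale_min, scale_max, polarity};
    function-polarity constructs are reversed at ingest so the model sees
    severity of the opposite construct.
    """
    with open(scales_yaml) as fh:
        scales = yaml.safe_load(fh)
    df = pd.read_csv(path, index_col=0)
    out = []
    for sid, row in df.iterrows():
        obs = {}
        for construct in df.columns:
            if construct not in scales:
                raise ProfileError(f"no scale config for construct {construct!r}")
            cfg = scales[construct]
            lv = discretize_score(float(row[construct]),
                                  float(cfg["scale_min"]), float(cfg["scale_max"]))
            if cfg.get("polarity", "severity") == "function":
                lv = reverse_function_scale(lv)
            obs[construct] = lv
        out.append(SubjectProfile(str(sid), obs))
    return out
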