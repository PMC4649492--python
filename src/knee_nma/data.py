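"""Arm-level randomized-trial data for the five-treatment knee-OA network.

The schema is long format, one row per trial arm. A row always carries the
trial id, the treatment label and the arm size; exactly one outcome payload
is filled in, depending on the outcome kind of the analysis:

* continuous change scores (pain, function): ``mean_change``, ``sd_change``,
  ``scale_max``;
* binary safety outcomes (withdrawals, SAEs, any/specific AEs): ``events``;
* joint-space width: ``mean_narrowing_mm``, ``sd_mm``.

Per-trial metadata (methodological quality, commercial support, baseline
pain severity) drives the sensitivity subsets and is repeated on every row
of a trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

#: Canonical treatment order. The first-listed treatment present in a trial
#: is that trial's baseline arm, and placebo is the network reference.
TREATMENTS: tuple[str, ...] = (
    "placebo",
    "glucosamine",
    "chondroitin",
    "glucosamine+chondroitin",
    "celecoxib",
)
TREATMENT_INDEX = {t: i for i, t in enumerate(TREATMENTS)}

CONTINUOUS_KINDS = frozenset({"pain_smd", "function_smd"})
BINARY_KINDS = frozenset({"withdrawal_ae", "serious_ae", "any_ae", "specific_ae"})
JSW_KINDS = frozenset({"jsw_md"})
OUTCOME_KINDS = CONTINUOUS_KINDS | BINARY_KINDS | JSW_KINDS

SCHEMA_COLUMNS: tuple[str, ...] = (
    "trial_id",
    "treatment",
    "n",
    "mean_change",
    "sd_change",
    "scale_max",
    "events",
    "mean_narrowing_mm",
    "sd_mm",
    "quality_flag",
    "commercial_support",
    "baseline_severe_pain",
)

SENSITIVITY_RULES = (
    "drop_poor_quality",
    "drop_no_commercial_support",
    "require_moderate_severe_pain",
)


class SchemaError(ValueError):
    """The input file does not match the documented column schema."""


class ValidationError(ValueError):
    """A row violates an arm- or trial-level invariant."""


class EmptyNetworkError(ValueError):
    """An operation produced a network with no trials."""


class DisconnectedNetworkError(ValueError):
    """The evidence graph is not a single connected component."""

    def __init__(self, components: list[set[str]]):
        self.components = components
        parts = "; ".join(sorted(",".join(sorted(c)) for c in components))
        super().__init__(f"evidence graph has {len(components)} components: {parts}")


def outcome_family(outcome_kind: str) -> str:
    """Map an outcome kind to its payload family: continuous, binary or jsw."""
    if outcome_kind in CONTINUOUS_KINDS:
        return "continuous"
    if outcome_kind in BINARY_KINDS:
        return "binary"
    if outcome_kind in JSW_KINDS:
        return "jsw"
    raise ValueError(f"unknown outcome kind {outcome_kind!r}")


@dataclass(frozen=True)
class TrialArm:
    trial_id: str
    treatment: str
    n: int
    # continuous payload
    mean_change: float | None = None
    sd_change: float | None = None
    scale_max: float | None = None
    # binary payload
    events: int | None = None
    # joint-space-width payload
    mean_narrowing_mm: float | None = None
    sd_mm: float | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENT_INDEX:
            raise ValidationError(
                f"trial {self.trial_id}: unknown treatment {self.treatment!r}"
            )
        if self.n <= 0:
            raise ValidationError(f"trial {self.trial_id}, arm {self.treatment}: n must be > 0")

    @property
    def outcome_type(self) -> str:
        if self.events is not None:
            return "binary"
        if self.mean_narrowing_mm is not None:
            return "jsw"
        return "continuous"

    def validate(self, family: str) -> None:
        """Check the payload required for ``family`` is present and coherent."""
        where = f"trial {self.trial_id}, arm {self.treatment}"
        if family == "continuous":
            if self.mean_change is None or self.sd_change is None or self.scale_max is None:
                raise ValidationError(f"{where}: continuous payload incomplete")
            if self.sd_change <= 0:
                raise ValidationError(f"{where}: sd_change must be > 0")
            if self.scale_max <= 0:
                raise ValidationError(f"{where}: scale_max must be > 0")
        elif family == "binary":
            if self.events is None:
                raise ValidationError(f"{where}: events missing")
            if self.events < 0:
                raise ValidationError(f"{where}: events must be >= 0")
            if self.events > self.n:
                raise ValidationError(f"{where}: events ({self.events}) > n ({self.n})")
        elif family == "jsw":
            if self.mean_narrowing_mm is None or self.sd_mm is None:
                raise ValidationError(f"{where}: jsw payload incomplete")
            if self.sd_mm <= 0:
                raise ValidationError(f"{where}: sd_mm must be > 0")
        else:  # pragma: no cover - guarded upstream
            raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class Trial:
    trial_id: str
    arms: tuple[TrialArm, ...]
    quality_flag: str = "adequate"  # {adequate, poor}
    commercial_support: str = "yes"  # {yes, no}
    baseline_severe_pain: str = "unknown"  # {yes, no, unknown}

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValidationError(f"trial {self.trial_id}: single-arm trial")
        treatments = [a.treatment for a in self.arms]
        if len(set(treatments)) != len(treatments):
            raise ValidationError(f"trial {self.trial_id}: duplicated treatment within trial")
        ordered = tuple(sorted(self.arms, key=lambda a: TREATMENT_INDEX[a.treatment]))
        object.__setattr__(self, "arms", ordered)
        if self.quality_flag not in ("adequate", "poor"):
            raise ValidationError(f"trial {self.trial_id}: bad quality_flag {self.quality_flag!r}")
        if self.commercial_support not in ("yes", "no"):
            raise ValidationError(
                f"trial {self.trial_id}: bad commercial_support {self.commercial_support!r}"
            )
        if self.baseline_severe_pain not in ("yes", "no", "unknown"):
            raise ValidationError(
                f"trial {self.trial_id}: bad baseline_severe_pain {self.baseline_severe_pain!r}"
            )

    @property
    def baseline(self) -> str:
        """Baseline treatment: the first arm in canonical order."""
        return self.arms[0].treatment

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(a.treatment for a in self.arms)

    @property
    def n_total(self) -> int:
        return sum(a.n for a in self.arms)


@dataclass(frozen=True)
class NetworkDataset:
    trials: tuple[Trial, ...]
    outcome_kind: str

    def __post_init__(self) -> None:
        if self.outcome_kind not in OUTCOME_KINDS:
            raise ValueError(f"unknown outcome kind {self.outcome_kind!r}")
        ordered = tuple(sorted(self.trials, key=lambda t: t.trial_id))
        object.__setattr__(self, "trials", ordered)
        family = outcome_family(self.outcome_kind)
        for trial in self.trials:
            for arm in trial.arms:
                arm.validate(family)

    @property
    def treatments(self) -> tuple[str, ...]:
        present = {a.treatment for t in self.trials for a in t.arms}
        return tuple(t for t in TREATMENTS if t in present)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_patients(self) -> int:
        return sum(t.n_total for t in self.trials)

    def graph(self) -> nx.Graph:
        """Evidence graph: nodes = treatments, edges annotated with the number
        of trials and participants contributing direct evidence."""
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for trial in self.trials:
            arms = trial.arms
            for i in range(len(arms)):
                for j in range(i + 1, len(arms)):
                    a, b = arms[i].treatment, arms[j].treatment
                    if g.has_edge(a, b):
                        g[a][b]["n_trials"] += 1
                        g[a][b]["n_patients"] += arms[i].n + arms[j].n
                    else:
                        g.add_edge(a, b, n_trials=1, n_patients=arms[i].n + arms[j].n)
        return g


@dataclass(frozen=True)
class ConnectivityReport:
    connected: bool
    components: tuple[frozenset[str], ...]
    edges: dict[tuple[str, str], dict[str, int]]

    def to_json(self) -> str:
        payload = {
            "connected": self.connected,
            "components": [sorted(c) for c in self.components],
            "edges": [
                {"treat_a": a, "treat_b": b, **attrs}
                for (a, b), attrs in sorted(self.edges.items())
            ],
        }
        return json.dumps(payload, indent=2)


def _parse_str(value, default=None):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    s = str(value).strip()
    return default if s == "" else s


def read_dataset(path: str | Path, outcome_kind: str) -> NetworkDataset:
    """Read a long-format arm-level CSV/TSV into a validated :class:`NetworkDataset`.

    Row order in the file never affects the result: trials are keyed by
    ``trial_id`` and arms ordered canonically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"trial_id": str, "treatment": str})
    return dataset_from_frame(df, outcome_kind)


def dataset_from_frame(df: pd.DataFrame, outcome_kind: str) -> NetworkDataset:
    """Build a dataset from an in-memory frame following the arm-level schema."""
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")
    extra = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected columns: {', '.join(extra)}")

    family = outcome_family(outcome_kind)
    trials: dict[str, dict] = {}
    for _, row in df.iterrows():
        tid = str(row["trial_id"]).strip()
        rec = trials.setdefault(
            tid,
            {
                "arms": [],
                "quality_flag": _parse_str(row["quality_flag"], "adequate"),
                "commercial_support": _parse_str(row["commercial_support"], "yes"),
                "baseline_severe_pain": _parse_str(row["baseline_severe_pain"], "unknown"),
            },
        )
        kwargs: dict = {"trial_id": tid, "treatment": str(row["treatment"]).strip()}
        try:
            kwargs["n"] = int(row["n"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"trial {tid}: non-integer n") from exc
        if family == "continuous":
            kwargs.update(
                mean_change=float(row["mean_change"]),
                sd_change=float(row["sd_change"]),
                scale_max=float(row["scale_max"]),
            )
        elif family == "binary":
            try:
                kwargs["events"] = int(row["events"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"trial {tid}: non-integer events") from exc
        else:
            kwargs.update(
                mean_narrowing_mm=float(row["mean_narrowing_mm"]),
                sd_mm=float(row["sd_mm"]),
            )
        rec["arms"].append(TrialArm(**kwargs))

    built = tuple(
        Trial(
            trial_id=tid,
            arms=tuple(rec["arms"]),
            quality_flag=rec["quality_flag"],
            commercial_support=rec["commercial_support"],
            baseline_severe_pain=rec["baseline_severe_pain"],
        )
        for tid, rec in trials.items()
    )
    return NetworkDataset(trials=built, outcome_kind=outcome_kind)


def dataset_to_frame(ds: NetworkDataset) -> pd.DataFrame:
    rows = []
    for trial in ds.trials:
        for arm in trial.arms:
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "treatment": arm.treatment,
                    "n": arm.n,
                    "mean_change": arm.mean_change,
                    "sd_change": arm.sd_change,
                    "scale_max": arm.scale_max,
                    "events": arm.events,
                    "mean_narrowing_mm": arm.mean_narrowing_mm,
                    "sd_mm": arm.sd_mm,
                    "quality_flag": trial.quality_flag,
                    "commercial_support": trial.commercial_support,
                    "baseline_severe_pain": trial.baseline_severe_pain,
                }
            )
    return pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))


def write_dataset(ds: NetworkDataset, path: str | Path) -> None:
    dataset_to_frame(ds).to_csv(path, index=False)


def check_connectivity(ds: NetworkDataset) -> ConnectivityReport:
    """Report whether the evidence graph is connected, its components, and the
    per-edge trial/participant annotation."""
    if not ds.trials:
        raise EmptyNetworkError("dataset has no trials")
    g = ds.graph()
    components = tuple(frozenset(c) for c in nx.connected_components(g))
    edges = {}
    for a, b, attrs in g.edges(data=True):
        key = tuple(sorted((a, b), key=lambda t: TREATMENT_INDEX[t]))
        edges[key] = {"n_trials": attrs["n_trials"], "n_patients": attrs["n_patients"]}
    return ConnectivityReport(connected=len(components) == 1, components=components, edges=edges)


def _passes(trial: Trial, rule: str) -> bool:
    if rule == "drop_poor_quality":
        return trial.quality_flag != "poor"
    if rule == "drop_no_commercial_support":
        return trial.commercial_support == "yes"
    if rule == "require_moderate_severe_pain":
        # positive evidence of moderate-to-severe baseline pain only
        return trial.baseline_severe_pain == "yes"
    raise ValueError(f"unknown sensitivity rule {rule!r}")


def apply_sensitivity_filter(ds: NetworkDataset, rule: str) -> tuple[NetworkDataset, int]:
    """Return (filtered dataset, number of excluded trials).

    Raises :class:`EmptyNetworkError` if no trials survive and
    :class:`DisconnectedNetworkError` if the surviving evidence graph splits.
    """
    kept = tuple(t for t in ds.trials if _passes(t, rule))
    excluded = len(ds.trials) - len(kept)
    if not kept:
        raise EmptyNetworkError(f"rule {rule!r} excluded all {len(ds.trials)} trials")
    filtered = NetworkDataset(trials=kept, outcome_kind=ds.outcome_kind)
    report = check_connectivity(filtered)
    if not report.connected:
        raise DisconnectedNetworkError([set(c) for c in report.components])
    return filtered, excluded
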