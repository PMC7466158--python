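"""Synthetic spontaneous-report generator with known interaction structure.

Generates JADER-shaped DEMO/DRUG/REAC tables (one row per case, per
suspect drug and per event respectively) from a declarative scenario:
independent per-drug exposure probabilities, a baseline target-event
probability (the f00-like cell), and per-pair cell probabilities
(f10, f01, f11) for declared drug pairs.  Each pair's ground-truth label
is derived from its configured cells: a pair is a true interaction iff
f11 strictly exceeds both the additive null (f10 + f01 - f00) and the
multiplicative null (f10 * f01 / f00).

Generation is fully reproducible from the scenario seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .contingency import (
    CaseReport,
    ColumnMap,
    ContingencyTable4x2,
    JADER_COLUMNS,
    TripleKey,
    normalize_drug,
    normalize_event,
    read_cases,
    tabulate_all,
)
from .evaluation import ConfusionCounts, MetricSet, confusion, metrics
from .signals import Algorithm, DEFAULT_ROR_CONFIG, RorConfig, detect_all

__all__ = [
    "DrugSpec",
    "InteractionSpec",
    "ScenarioConfig",
    "SyntheticDataset",
    "RecoveryResult",
    "generate",
    "write_dataset",
    "recovery_experiment",
    "demo_scenario",
    "null_scenario",
]

#: Pooled pseudo-event giving the "other AEs" column non-trivial counts.
OTHER_EVENT = "Other adverse events (pooled)"


class DrugSpec(BaseModel):
    """One drug: marginal suspect-exposure probability and optional baseline risk."""

    name: str
    exposure_prob: float = Field(gt=0.0, lt=1.0)
    risk_multiplier: float = Field(default=1.0, gt=0.0)

    @field_validator("name")
    @classmethod
    def _normalize(cls, v: str) -> str:
        norm = normalize_drug(v)
        if not norm:
            raise ValueError("drug name must be non-empty")
        return norm


class InteractionSpec(BaseModel):
    """Cell probabilities for one declared drug pair."""

    drug1: str
    drug2: str
    f10: float = Field(gt=0.0, lt=1.0)
    f01: float = Field(gt=0.0, lt=1.0)
    f11: float = Field(ge=0.0, lt=1.0)

    @field_validator("drug1", "drug2")
    @classmethod
    def _normalize(cls, v: str) -> str:
        return normalize_drug(v)

    @model_validator(mode="after")
    def _canonical(self) -> "InteractionSpec":
        if self.drug1 == self.drug2:
            raise ValueError("interaction pair must name two distinct drugs")
        if self.drug1 > self.drug2:
            self.drug1, self.drug2 = self.drug2, self.drug1
            self.f10, self.f01 = self.f01, self.f10
        return self


class ScenarioConfig(BaseModel):
    """Declarative scenario for one synthetic dataset."""

    n_cases: int = Field(gt=0)
    drugs: list[DrugSpec] = Field(min_length=1)
    target_event: str
    baseline_event_prob: float = Field(gt=0.0, lt=1.0)
    interaction_pairs: list[InteractionSpec] = Field(default_factory=list)
    other_event_prob: float = Field(default=0.85, gt=0.0, lt=1.0)
    seed: int = 0

    @field_validator("target_event")
    @classmethod
    def _event(cls, v: str) -> str:
        norm = normalize_event(v)
        if not norm:
            raise ValueError("target_event must be non-empty")
        return norm

    @model_validator(mode="after")
    def _consistent(self) -> "ScenarioConfig":
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in scenario")
        declared = set(names)
        for pair in self.interaction_pairs:
            for d in (pair.drug1, pair.drug2):
                if d not in declared:
                    raise ValueError(f"interaction pair references undeclared drug {d!r}")
        keys = [(p.drug1, p.drug2) for p in self.interaction_pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate interaction pair in scenario")
        for d in self.drugs:
            if self.baseline_event_prob * d.risk_multiplier >= 1.0:
                raise ValueError(f"risk multiplier for {d.name!r} pushes event probability to 1")
        return self

    # --- pair diagnostics --------------------------------------------------
    def pair_nulls(self, pair: InteractionSpec) -> dict[str, float | bool]:
        """Additive/multiplicative null values for one pair and where f11 sits."""
        f00 = self.baseline_event_prob
        additive = pair.f10 + pair.f01 - f00
        multiplicative = pair.f10 * pair.f01 / f00
        tol = 1e-9
        return {
            "additive_null": additive,
            "multiplicative_null": multiplicative,
            "on_additive_null": math.isclose(pair.f11, additive, rel_tol=tol, abs_tol=tol),
            "on_multiplicative_null": math.isclose(pair.f11, multiplicative, rel_tol=tol, abs_tol=tol),
            "is_interaction": pair.f11 > additive + tol and pair.f11 > multiplicative + tol,
        }

    def describe_pairs(self) -> pd.DataFrame:
        """Per-pair diagnostics: configured cells, both nulls, truth label."""
        rows = []
        for pair in sorted(self.interaction_pairs, key=lambda p: (p.drug1, p.drug2)):
            rows.append(
                {
                    "drug1": pair.drug1,
                    "drug2": pair.drug2,
                    "f00": self.baseline_event_prob,
                    "f10": pair.f10,
                    "f01": pair.f01,
                    "f11": pair.f11,
                    **self.pair_nulls(pair),
                }
            )
        return pd.DataFrame(rows)

    def ground_truth(self) -> list[TripleKey]:
        """Configured pairs whose f11 exceeds both interaction nulls."""
        return sorted(
            TripleKey(p.drug1, p.drug2, self.target_event)
            for p in self.interaction_pairs
            if self.pair_nulls(p)["is_interaction"]
        )

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, ensure_ascii=False)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated tables plus the implied case records and ground truth."""

    config: ScenarioConfig
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    cases: tuple[CaseReport, ...]
    ground_truth: tuple[TripleKey, ...]


def _event_probabilities(config: ScenarioConfig, exposed: np.ndarray) -> np.ndarray:
    """Per-case target-event probability from the exposure matrix.

    Priority: a pair with both drugs exposed assigns its f11 (pairs
    scanned in canonical order, first match wins); otherwise a pair with
    exactly one drug exposed assigns its f10/f01; otherwise the baseline
    times the largest risk multiplier among exposed drugs.
    """
    n = exposed.shape[0]
    index = {d.name: i for i, d in enumerate(config.drugs)}
    probs = np.full(n, config.baseline_event_prob)
    for i, d in enumerate(config.drugs):
        if d.risk_multiplier != 1.0:
            boosted = min(config.baseline_event_prob * d.risk_multiplier, 1.0 - 1e-9)
            probs = np.where(exposed[:, i], np.maximum(probs, boosted), probs)

    pairs = sorted(config.interaction_pairs, key=lambda p: (p.drug1, p.drug2))
    assigned = np.zeros(n, dtype=bool)
    for pair in pairs:
        e1 = exposed[:, index[pair.drug1]]
        e2 = exposed[:, index[pair.drug2]]
        both = e1 & e2 & ~assigned
        probs[both] = pair.f11
        assigned |= both
    for pair in pairs:
        e1 = exposed[:, index[pair.drug1]]
        e2 = exposed[:, index[pair.drug2]]
        only1 = e1 & ~e2 & ~assigned
        only2 = e2 & ~e1 & ~assigned
        probs[only1] = pair.f10
        probs[only2] = pair.f01
        assigned |= only1 | only2
    return probs


def generate(config: ScenarioConfig, columns: ColumnMap = JADER_COLUMNS) -> SyntheticDataset:
    """Draw one dataset: exposures, events, and the three csv-shaped tables."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drug_names = [d.name for d in config.drugs]

    exposure_probs = np.array([d.exposure_prob for d in config.drugs])
    exposed = rng.random((n, len(drug_names))) < exposure_probs
    target = rng.random(n) < _event_probabilities(config, exposed)
    other = rng.random(n) < config.other_event_prob

    width = max(6, len(str(n)))
    case_ids = np.array([f"C{i + 1:0{width}d}" for i in range(n)])

    demo = pd.DataFrame({columns.case_id: case_ids})

    case_idx, drug_idx = np.nonzero(exposed)
    drug = pd.DataFrame(
        {
            columns.case_id: case_ids[case_idx],
            columns.drug_name: [drug_names[j] for j in drug_idx],
            columns.drug_role: columns.suspect_role_value,
        }
    )

    reac_rows = []
    for mask, term in ((target, config.target_event), (other, OTHER_EVENT)):
        idx = np.nonzero(mask)[0]
        reac_rows.append(
            pd.DataFrame({columns.case_id: case_ids[idx], columns.event_pt: term})
        )
    reac = (
        pd.concat(reac_rows, ignore_index=True)
        .sort_values(columns.case_id, kind="stable")
        .reset_index(drop=True)
    )

    drug_sets = [frozenset(drug_names[j] for j in np.nonzero(exposed[i])[0]) for i in range(n)]
    cases = tuple(
        CaseReport(
            case_ids[i],
            drug_sets[i],
            frozenset(
                ([config.target_event] if target[i] else []) + ([OTHER_EVENT] if other[i] else [])
            ),
        )
        for i in range(n)
    )

    return SyntheticDataset(
        config=config,
        demo=demo,
        drug=drug,
        reac=reac,
        cases=cases,
        ground_truth=tuple(config.ground_truth()),
    )


def write_dataset(
    dataset: SyntheticDataset, outdir: "str | Path", columns: ColumnMap = JADER_COLUMNS
) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC plus ground_truth.csv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("DEMO", dataset.demo), ("DRUG", dataset.drug), ("REAC", dataset.reac)):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        paths[name] = path
    truth = pd.DataFrame(
        [{"drug1": t.drug1, "drug2": t.drug2, "event": t.event} for t in dataset.ground_truth],
        columns=["drug1", "drug2", "event"],
    )
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False, encoding="utf-8", lineterminator="\n")
    paths["ground_truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# end-to-end recovery experiment
# ---------------------------------------------------------------------------

DEFAULT_ALGORITHMS = (
    Algorithm.SUBSET_PREVIOUS,
    Algorithm.SUBSET_NEW,
    Algorithm.OMEGA,
    Algorithm.ADDITIVE,
    Algorithm.MULTIPLICATIVE,
    Algorithm.CHI_SQUARE,
)


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of generate -> tabulate -> detect -> score for one scenario."""

    dataset: SyntheticDataset
    universe: tuple[TripleKey, ...]
    tables: dict[TripleKey, ContingencyTable4x2]
    signal_sets: dict[Algorithm, set[TripleKey]]
    confusions: dict[Algorithm, ConfusionCounts]
    metric_sets: dict[Algorithm, MetricSet]
    summary: pd.DataFrame


def recovery_experiment(
    config: ScenarioConfig,
    algorithms: Sequence[Algorithm] = DEFAULT_ALGORITHMS,
    ror_config: RorConfig = DEFAULT_ROR_CONFIG,
    use_parser: bool = False,
) -> RecoveryResult:
    """Generate a scenario and score every requested detector against truth.

    The triple universe is the set of configured pairs.  ``use_parser``
    routes the generated tables through the csv-layout reader instead of
    the in-memory case records (identical content; exercises the parser).
    """
    if not config.interaction_pairs:
        raise ValueError("recovery experiment needs at least one configured pair")
    dataset = generate(config)
    cases = (
        read_cases(dataset.demo, dataset.drug, dataset.reac) if use_parser else list(dataset.cases)
    )
    universe = tuple(
        sorted(
            TripleKey(p.drug1, p.drug2, config.target_event)
            for p in config.interaction_pairs
        )
    )
    tables = tabulate_all(cases, universe)
    truth = set(dataset.ground_truth)

    signal_sets: dict[Algorithm, set[TripleKey]] = {}
    confusions: dict[Algorithm, ConfusionCounts] = {}
    metric_sets: dict[Algorithm, MetricSet] = {}
    rows = []
    for alg in algorithms:
        verdicts = detect_all(tables, alg, ror_config)
        flagged = {t for t, v in verdicts.items() if v.signal}
        signal_sets[alg] = flagged
        counts = confusion(flagged, truth, universe)
        confusions[alg] = counts
        mset = metrics(counts)
        metric_sets[alg] = mset
        rows.append(
            {
                "algorithm": alg.value,
                "tp": counts.tp,
                "fp": counts.fp,
                "tn": counts.tn,
                "fn": counts.fn,
                **mset.rounded(3),
            }
        )
    summary = pd.DataFrame(rows)
    return RecoveryResult(
        dataset=dataset,
        universe=universe,
        tables=tables,
        signal_sets=signal_sets,
        confusions=confusions,
        metric_sets=metric_sets,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------

def demo_scenario(seed: int = 20200812, n_cases: int = 50_000) -> ScenarioConfig:
    """Packaged demo: one injected interaction pair among five null pairs.

    The injected pair (drug_a01, drug_a02) carries cells
    (f00, f10, f01, f11) = (0.01, 0.05, 0.05, 0.30), well above both
    interaction nulls; the five remaining pairs sit exactly on both
    nulls (all cells equal to the baseline).
    """
    drugs = [
        DrugSpec(name=f"drug_a{i:02d}", exposure_prob=p)
        for i, p in enumerate(
            (0.05, 0.05, 0.08, 0.08, 0.10, 0.10, 0.06, 0.06, 0.12, 0.12, 0.07, 0.07), start=1
        )
    ]
    f00 = 0.01
    pairs = [
        InteractionSpec(drug1="drug_a01", drug2="drug_a02", f10=0.05, f01=0.05, f11=0.30)
    ]
    for i in (3, 5, 7, 9, 11):
        pairs.append(
            InteractionSpec(
                drug1=f"drug_a{i:02d}", drug2=f"drug_a{i + 1:02d}", f10=f00, f01=f00, f11=f00
            )
        )
    return ScenarioConfig(
        n_cases=n_cases,
        drugs=drugs,
        target_event="Stevens-Johnson syndrome",
        baseline_event_prob=f00,
        interaction_pairs=pairs,
        seed=seed,
    )


def null_scenario(seed: int = 0, n_cases: int = 20_000) -> ScenarioConfig:
    """Pure-null scenario: every pair sits exactly on both interaction nulls.

    Exposures are kept rare (5%) so the non-co-exposed rows dwarf the
    co-exposure row; the chi-square model treats its expected count as
    known, so this is the regime where its nominal level holds.
    """
    f00 = 0.05
    drugs = [DrugSpec(name=f"drug_n{i:02d}", exposure_prob=0.05) for i in range(1, 7)]
    pairs = [
        InteractionSpec(
            drug1=f"drug_n{i:02d}", drug2=f"drug_n{i + 1:02d}", f10=f00, f01=f00, f11=f00
        )
        for i in (1, 3, 5)
    ]
    return ScenarioConfig(
        n_cases=n_cases,
        drugs=drugs,
        target_event="Stevens-Johnson syndrome",
        baseline_event_prob=f00,
        interaction_pairs=pairs,
        seed=seed,
    )
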