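"""Carbon-source growth phenotyping and prediction scoring.

Growth on each carbon source is simulated on a minimal medium: every
carbon-bearing exchange is closed, the assayed source is opened at a fixed
uptake, and growth is maximised; the call is positive when the growth rate
clears a threshold. Predicted calls are scored against an observed table as
a 2x2 confusion summary with accuracy in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from cobra import Model

from hydrogem.ec_builder import EcModel, as_cobra
from hydrogem.model_core import reaction_kind

__all__ = [
    "PhenotypeTable",
    "ConfusionSummary",
    "GROWTH_CALL_THRESHOLD",
    "carbon_source_growth",
    "simulate_phenotypes",
    "phenotype_accuracy",
]

#: minimum simulated growth rate (1/h) for a positive call
GROWTH_CALL_THRESHOLD = 0.01


@dataclass
class PhenotypeTable:
    """Observed growth calls per carbon source.

    Backed by a DataFrame with columns source_name, exchange_reaction_id,
    observed_growth; ``provenance`` records the experimental call rule.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"source_name", "exchange_reaction_id", "observed_growth"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        if self.frame["exchange_reaction_id"].duplicated().any():
            raise ValueError("duplicate exchange ids in phenotype table")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"), provenance=provenance)

    def to_tsv(self, path: str | Path) -> Path:
        self.frame.to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass
class ConfusionSummary:
    """2x2 contingency of observed vs simulated growth calls."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        """Overall prediction accuracy in percent."""
        return 100.0 * (self.tp + self.tn) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
              "accuracy_percent": self.accuracy}]
        )


def carbon_source_growth(
    model: Model | EcModel,
    exchange_id: str,
    uptake: float = 10.0,
    threshold: float = GROWTH_CALL_THRESHOLD,
) -> tuple[bool, float]:
    """Simulate growth with the named exchange as sole carbon source."""
    m = as_cobra(model)
    if exchange_id not in m.reactions:
        raise KeyError(f"unknown exchange reaction {exchange_id}")
    with m:
        for rxn in m.reactions:
            if reaction_kind(rxn) != "exchange":
                continue
            met = next(iter(rxn.metabolites))
            if met.formula and "C" in met.elements:
                rxn.lower_bound = 0.0
        m.reactions.get_by_id(exchange_id).lower_bound = -abs(uptake)
        growth = m.slim_optimize(error_value=0.0)
    growth = max(float(growth), 0.0)
    return growth >= threshold, growth


def simulate_phenotypes(
    model: Model | EcModel,
    table: PhenotypeTable,
    uptake: float = 10.0,
    threshold: float = GROWTH_CALL_THRESHOLD,
) -> dict[str, bool]:
    """Predicted growth call for every row of an observed table."""
    return {
        row.exchange_reaction_id: carbon_source_growth(
            model, row.exchange_reaction_id, uptake=uptake, threshold=threshold
        )[0]
        for row in table.frame.itertuples()
    }


def phenotype_accuracy(
    predictions: Mapping[str, bool], table: PhenotypeTable
) -> ConfusionSummary:
    """Score predictions against observations; every row needs a prediction."""
    missing = [
        rid for rid in table.frame["exchange_reaction_id"]
        if rid not in predictions
    ]
    if missing:
        raise KeyError(f"missing predictions for {missing}")
    tp = tn = fp = fn = 0
    for row in table.frame.itertuples():
        observed = bool(row.observed_growth)
        predicted = bool(predictions[row.exchange_reaction_id])
        if observed and predicted:
            tp += 1
        elif not observed and not predicted:
            tn += 1
        elif predicted:
            fp += 1
        else:
            fn += 1
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn)
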