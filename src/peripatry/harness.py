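"""Hierarchical multi-model selection over population pairs.

The study design this orchestrates: first test the peripatric-speciation
hypothesis on the full species pair (mainland = ancestral population 2,
island = derived population 1) against a candidate set spanning vicariance,
founder and old-founder scenarios; then run two further pairwise comparisons
of the island population against each mainland subgroup using the standard
secondary-contact / isolation / size-change model set, to ask whether gene
flow was periodic after an initial period of isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .fit import (
    DEFAULT_PERTURB_FOLDS,
    DEFAULT_ROUNDS,
    EngineConfig,
    FitResult,
    OptimizationError,
    aic_weights,
    optimize_model,
)
from .models import get_model
from .sfs import JointSFS

__all__ = [
    "MODEL_SETS",
    "SelectionConfig",
    "ComparisonReport",
    "run_comparison",
    "run_hierarchical",
    "HIERARCHICAL_LABELS",
]

log = logging.getLogger(__name__)

MODEL_SETS: Dict[str, List[str]] = {
    # comparison 1: vicariance vs founder vs old-founder scenarios
    "founder_set": [
        "no_mig",
        "sym_mig",
        "asym_mig",
        "vic_no_mig",
        "founder_nomig",
        "founder_sym",
        "founder_asym",
        "founder_sec_contact_asym_two_epoch",
    ],
    # comparisons 2-3: secondary contact / isolation / size change
    "secondary_contact_set": [
        "no_mig",
        "sym_mig",
        "asym_mig",
        "anc_sym_mig",
        "anc_asym_mig",
        "sec_contact_sym_mig",
        "sec_contact_asym_mig",
        "sec_contact_sym_mig_size",
        "sec_contact_asym_mig_size",
        "sec_contact_sym_mig_size_three_epoch",
        "sec_contact_asym_mig_size_three_epoch",
    ],
}

# replicate total of the reference four-round schedule; configs below this
# are flagged as low-effort in reports
_FULL_EFFORT_REPLICATES = sum(DEFAULT_ROUNDS)

HIERARCHICAL_LABELS: Tuple[str, str, str] = (
    "species_pair",
    "balkanic_pannonian",
    "central_asian_pontic",
)


@dataclass
class SelectionConfig:
    rounds: Tuple[int, ...] = DEFAULT_ROUNDS
    perturb_folds: Tuple[float, ...] = DEFAULT_PERTURB_FOLDS
    engine: EngineConfig = field(default_factory=EngineConfig)
    seed: int = 0

    def snapshot(self) -> dict:
        return {
            "rounds": list(self.rounds),
            "perturb_folds": list(self.perturb_folds),
            "engine": asdict(self.engine),
            "seed": self.seed,
        }


@dataclass
class ComparisonReport:
    """Ranked model table for one population pair."""

    pair_label: str
    rows: List[dict]  # per model: name, k, loglik, theta, aic, delta_aic, weight, params
    winner: str
    failed: Dict[str, str]
    config: dict
    seeds: Dict[str, int]
    low_effort: bool = False
    tie_broken: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def weight_of(self, model_name: str) -> float:
        for row in self.rows:
            if row["model"] == model_name:
                return row["weight"]
        raise KeyError(model_name)

    @property
    def fits(self) -> Dict[str, dict]:
        return {row["model"]: row for row in self.rows}


def run_comparison(
    data: JointSFS,
    model_names: Sequence[str],
    config: Optional[SelectionConfig] = None,
    pair_label: str = "pair",
) -> ComparisonReport:
    """Fit every candidate model and rank by AIC with Akaike weights.

    Each model gets an independent fitting seed derived from the config
    seed; all models share one high-replicate refit seed so their reported
    likelihoods are evaluated under identical Monte-Carlo randomness. A
    model that errors is recorded as failed and excluded from the weights.
    """
    config = config or SelectionConfig()
    for name in model_names:
        get_model(name)  # fail fast on unknown names
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    refit_seed = int(rng.integers(2**31))
    model_seeds = {name: int(rng.integers(2**31)) for name in model_names}
    fits: List[FitResult] = []
    failed: Dict[str, str] = {}
    for name in model_names:
        try:
            fits.append(
                optimize_model(
                    name,
                    data,
                    rounds=config.rounds,
                    perturb_folds=config.perturb_folds,
                    seed=model_seeds[name],
                    engine_config=config.engine,
                    refit_seed=refit_seed,
                )
            )
            log.info("%s: fitted %s, ll=%.2f", pair_label, name, fits[-1].loglik)
        except (OptimizationError, ValueError) as exc:
            failed[name] = str(exc)
            log.warning("%s: model %s failed: %s", pair_label, name, exc)
    if not fits:
        raise OptimizationError(f"all models failed for {pair_label}", [])
    if failed:
        log.warning("%s: weights renormalized over %d successful fits", pair_label, len(fits))
    weights = aic_weights(fits)
    # rank by AIC; ties by fewer free parameters, then name
    order = sorted(fits, key=lambda f: (f.aic, f.k, f.model_name))
    tie_broken = len(order) > 1 and np.isclose(order[0].aic, order[1].aic)
    if tie_broken:
        log.info("%s: AIC tie broken by parameter count / name order", pair_label)
    min_aic = order[0].aic
    rows = [
        {
            "model": f.model_name,
            "k": f.k,
            "loglik": f.loglik,
            "theta": f.theta_hat,
            "aic": f.aic,
            "delta_aic": f.aic - min_aic,
            "weight": weights[f.model_name],
            "params": f.params_hat,
        }
        for f in order
    ]
    return ComparisonReport(
        pair_label=pair_label,
        rows=rows,
        winner=order[0].model_name,
        failed=failed,
        config=config.snapshot(),
        seeds={"refit": refit_seed, **model_seeds},
        low_effort=sum(config.rounds) < _FULL_EFFORT_REPLICATES,
        tie_broken=bool(tie_broken),
    )


def run_hierarchical(
    datasets: Mapping[str, JointSFS],
    config: Optional[SelectionConfig] = None,
    model_sets: Optional[Mapping[str, Sequence[str]]] = None,
) -> Tuple[List[ComparisonReport], "object"]:
    """Run the three-comparison hierarchical design.

    ``datasets`` must carry the labels ``species_pair`` (island vs full
    mainland; founder/vicariance/old-founder candidate set) and
    ``balkanic_pannonian`` / ``central_asian_pontic`` (island vs mainland
    subgroup; secondary-contact candidate set). Labels are propagated
    verbatim. Returns the three reports plus a combined summary DataFrame.
    """
    import pandas as pd

    config = config or SelectionConfig()
    missing = [lbl for lbl in HIERARCHICAL_LABELS if lbl not in datasets]
    if missing:
        raise KeyError(f"missing dataset label(s): {missing}")
    sets = {
        "species_pair": MODEL_SETS["founder_set"],
        "balkanic_pannonian": MODEL_SETS["secondary_contact_set"],
        "central_asian_pontic": MODEL_SETS["secondary_contact_set"],
    }
    if model_sets:
        sets.update({k: list(v) for k, v in model_sets.items()})
    reports = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA1]))
    for lbl in HIERARCHICAL_LABELS:
        sub = SelectionConfig(
            rounds=config.rounds,
            perturb_folds=config.perturb_folds,
            engine=config.engine,
            seed=int(rng.integers(2**31)),
        )
        reports.append(run_comparison(datasets[lbl], sets[lbl], sub, pair_label=lbl))
    summary = pd.concat(
        [r.to_dataframe().assign(pair=r.pair_label) for r in reports], ignore_index=True
    )
    return reports, summary
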