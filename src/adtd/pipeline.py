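"""End-to-end experiment driver: simulate -> train weights -> deconvolve
-> evaluate, plus the hyperparameter grid."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .dtd import DTDModel
from .evaluate import (EvaluationReport, hidden_recovery, profile_recovery,
                       recovery_correlations, regulation_auc)
from .io import RunConfig, write_gene_weights, write_manifest, write_matrix_tsv
from .model import ADTDModel

__all__ = ["simulate_dataset", "run_pipeline", "hyperparameter_grid"]

logger = logging.getLogger(__name__)


def _derive_seed(seed: int, offset: int) -> int:
    return int(np.random.default_rng([seed, offset]).integers(2**31 - 1))


def simulate_dataset(config: RunConfig, seed: int | None = None) -> dict:
    """Generate a full synthetic study: population, reference, training
    mixtures (no hidden cells, no regulation), and validation mixtures
    with hidden background and spiked regulation."""
    seed = config.seed if seed is None else seed
    celltypes = [f"ct{k}" for k in range(config.q)] + ["hidden"]
    pop = sim.generate_population(
        p=config.p,
        celltypes=celltypes,
        cells_per_type=config.cells_per_type,
        separation=config.separation,
        noise_dispersion=config.noise_dispersion,
        type_jitter=config.type_jitter,
        housekeeping_fraction=config.housekeeping_fraction,
        seed=_derive_seed(seed, 0),
        hidden_celltypes=("hidden",),
    )
    X = sim.build_reference(pop)
    Y_train, truth_train = sim.sample_mixtures(
        pop, n=config.n_train, cells_per_mixture=config.cells_per_mixture,
        hidden_fraction_mean=0.0, seed=_derive_seed(seed, 1))
    Y_val, truth_val = sim.sample_mixtures(
        pop, n=config.n, cells_per_mixture=config.cells_per_mixture,
        hidden_fraction_mean=config.hidden_fraction,
        seed=_derive_seed(seed, 2))
    spec = None
    if config.n_specific + config.n_unspecific > 0:
        spec = sim.make_regulation_spec(
            X, n_specific=config.n_specific, n_unspecific=config.n_unspecific,
            top_per_type=config.top_per_type,
            unspecific_pool_size=config.unspecific_pool_size,
            factors=config.factors, seed=_derive_seed(seed, 3))
        Y_val = sim.spike_regulation(Y_val, X, truth_val.C_true, spec)
        truth_val.regulation = spec
    return {
        "population": pop,
        "X": X,
        "Y_train": Y_train,
        "truth_train": truth_train,
        "Y_val": Y_val,
        "truth_val": truth_val,
        "regulation": spec,
    }


def _evaluate_fit(result, truth, celltype_ids=None) -> EvaluationReport:
    per_type, mean_r = recovery_correlations(truth.C_true, result.C,
                                             celltype_ids=celltype_ids)
    hid = hidden_recovery(truth.hidden_true, result.hidden_weights)
    prof = profile_recovery(truth.x_true, result.x)
    auc = None
    if truth.regulation is not None and truth.regulation.entries:
        auc = regulation_auc(result.Delta, truth.regulation)
    return EvaluationReport(per_type_r=per_type, mean_r=mean_r, hidden_r=hid,
                            profile_r=prof, regulation_auc=auc)


def run_pipeline(config: RunConfig, out_dir=None, write: bool = True) -> dict:
    """Execute the full synthetic study and (optionally) write artifacts.

    Returns a dict with the evaluation report, the fitted objects and the
    dataset; identical config + seed reproduces identical numbers.
    """
    out = Path(out_dir or config.out_dir)
    stage = "simulate"
    try:
        data = simulate_dataset(config)
        stage = "train-weights"
        dtd = DTDModel(data["X"].to_numpy(), data["Y_train"].to_numpy(),
                       data["truth_train"].C_true,
                       gene_ids=list(data["X"].index)).fit()
        stage = "deconvolve"
        model = ADTDModel(data["Y_val"], data["X"],
                          gene_weights=dtd.gene_weights,
                          lambda1=config.lambda1, lambda2=config.lambda2,
                          max_iter=config.max_iter, tol=config.tol)
        result = model.fit()
        stage = "evaluate"
        report = _evaluate_fit(result, data["truth_val"],
                               celltype_ids=list(data["X"].columns))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    if write:
        write_matrix_tsv(data["X"], out / "X.tsv")
        write_matrix_tsv(data["Y_val"], out / "Y.tsv")
        write_gene_weights(dtd.gene_weights, data["X"].index,
                           out / "g.tsv")
        write_matrix_tsv(result.composition_frame(), out / "C.tsv")
        write_matrix_tsv(
            pd.DataFrame({"x": result.x}, index=data["X"].index),
            out / "x.tsv")
        write_matrix_tsv(
            pd.DataFrame(result.Delta, index=data["X"].index,
                         columns=data["X"].columns), out / "Delta.tsv")
        write_matrix_tsv(
            pd.DataFrame([result.hidden_weights],
                         columns=data["Y_val"].columns, index=["hidden"]),
            out / "hidden.tsv")
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True))
        write_manifest(out, config, extra={
            "loss_trace_final": result.loss,
            "n_iter": result.n_iter,
            "converged": result.converged,
        })
    return {"report": report, "result": result, "dtd": dtd, "data": data}


def hyperparameter_grid(config: RunConfig, lambda1_list, lambda2_list,
                        data: dict | None = None) -> pd.DataFrame:
    """Fit and evaluate every (lambda1, lambda2) pair on shared data.

    ``inf`` is accepted symbolically in either list.  Failures of single
    cells are recorded (``error`` column) and the grid continues.
    """
    if data is None:
        data = simulate_dataset(config)
    dtd = DTDModel(data["X"].to_numpy(), data["Y_train"].to_numpy(),
                   data["truth_train"].C_true).fit()
    rows = []
    for l1 in lambda1_list:
        for l2 in lambda2_list:
            row = {"lambda1": float(l1), "lambda2": float(l2)}
            try:
                model = ADTDModel(data["Y_val"], data["X"],
                                  gene_weights=dtd.gene_weights,
                                  lambda1=float(l1), lambda2=float(l2),
                                  max_iter=config.max_iter, tol=config.tol)
                rep = _evaluate_fit(model.fit(), data["truth_val"],
                                    celltype_ids=list(data["X"].columns))
                row.update(rep.to_dict())
            except Exception as exc:  # keep scanning the grid
                logger.warning("grid cell (%s, %s) failed: %s", l1, l2, exc)
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
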