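"""Training/prediction scenarios, accuracy and gain statistics, experiment runner.

A scenario fixes which cycles train the model, which cycle is predicted, and
what fraction of the prediction cycle augments the training set.  The
prediction cycle is split 85/15 (85% rounded to the nearest line count); the
augmentation takes the first ceil(fraction * cycle size) lines of the 15%
remainder, so the 5% subset is nested in the 10% subset is nested in the 15%
subset within a partition.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels as kmod
from . import predictors as pmod
from . import varcomp as vmod
from .simdata import SimulatedPopulation

__all__ = [
    "Scenario",
    "AccuracyResult",
    "build_scenario",
    "partition_population",
    "accuracy",
    "gain_statistics",
    "run_experiment",
    "summarize_results",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class Scenario:
    training_cycles: tuple
    prediction_cycle: object
    augmentation_fraction: float
    seed: int
    n_ps: int
    n_remainder: int
    n_aug: int
    n_ts: int

    @property
    def label(self) -> str:
        base = "+".join(str(c) for c in self.training_cycles)
        return f"{base}|aug{int(round(100 * self.augmentation_fraction))}%"


@dataclass
class AccuracyResult:
    model: str
    scenario: str
    rho: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.rho))

    @property
    def sd(self) -> float:
        return float(np.std(self.rho, ddof=1)) if len(self.rho) > 1 else 0.0


def build_scenario(
    cycle_sizes: dict,
    training_cycles,
    augmentation_fraction: float,
    prediction_cycle,
    seed: int = 0,
) -> Scenario:
    """Scenario arithmetic from per-cycle line counts.

    The prediction cycle of size N splits into a prediction set of
    ``round(0.85 N)`` lines and a remainder; the augmentation adds
    ``ceil(fraction * N)`` remainder lines to the training cycles' total.
    """
    training_cycles = tuple(training_cycles)
    if prediction_cycle in training_cycles:
        raise ValueError("prediction cycle cannot also be a training cycle")
    missing = [c for c in (*training_cycles, prediction_cycle) if c not in cycle_sizes]
    if missing:
        raise ValueError(f"unknown cycles: {missing}")
    if augmentation_fraction < 0:
        raise ValueError("augmentation fraction must be non-negative")
    size = int(cycle_sizes[prediction_cycle])
    n_ps = _round_half_away(0.85 * size)
    n_rem = size - n_ps
    n_aug = int(math.ceil(augmentation_fraction * size))
    if n_aug > n_rem:
        # a fraction up to the held-out share means "the whole remainder"
        # (rounding can make ceil(f*N) exceed N - round(0.85*N) by one)
        if augmentation_fraction <= 0.15 + 1e-12:
            n_aug = n_rem
        else:
            raise ValueError(
                f"augmentation needs {n_aug} lines but only {n_rem} are held out"
            )
    n_ts = int(sum(cycle_sizes[c] for c in training_cycles)) + n_aug
    return Scenario(
        training_cycles=training_cycles,
        prediction_cycle=prediction_cycle,
        augmentation_fraction=augmentation_fraction,
        seed=seed,
        n_ps=n_ps,
        n_remainder=n_rem,
        n_aug=n_aug,
        n_ts=n_ts,
    )


def partition_population(
    population: SimulatedPopulation, scenario: Scenario
) -> tuple[np.ndarray, np.ndarray]:
    """Realize (training_ids, prediction_ids) for a scenario on a population.

    The prediction cycle's lines are permuted with the scenario seed; the
    first ``n_ps`` become the prediction set and the next ``n_aug`` join the
    training set (nested augmentation across fractions at a fixed seed).
    """
    cycles = population.cycles
    ids = population.ids
    pred_pool = ids[cycles == scenario.prediction_cycle]
    if len(pred_pool) != scenario.n_ps + scenario.n_remainder:
        raise ValueError("population cycle size does not match the scenario")
    rng = np.random.default_rng(scenario.seed)
    perm = rng.permutation(len(pred_pool))
    ps_ids = pred_pool[perm[: scenario.n_ps]]
    aug_ids = pred_pool[perm[scenario.n_ps: scenario.n_ps + scenario.n_aug]]
    base = ids[np.isin(cycles, scenario.training_cycles)]
    ts_ids = np.concatenate([base, aug_ids])
    return ts_ids, ps_ids


def accuracy(y_ps: np.ndarray, u_hat: np.ndarray) -> float:
    """Pearson correlation between observed and predicted values."""
    y = np.asarray(y_ps, dtype=float)
    u = np.asarray(u_hat, dtype=float)
    if y.size != u.size:
        raise ValueError("vectors must have equal length")
    if y.size < 3:
        raise ValueError("need at least three prediction individuals")
    if y.std() == 0 or u.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(y, u)[0, 1])


def gain_statistics(acc_gblup: float, acc_kblup: float, acc_blup: float,
                    acc_ssi: float) -> tuple[float, float]:
    """(Gain1, Gain2) in percent: KBLUP vs GBLUP, and SSI vs the matching BLUP."""
    if acc_gblup == 0 or acc_blup == 0:
        raise ZeroDivisionError("gain undefined for zero baseline accuracy")
    gain1 = 100.0 * (acc_kblup - acc_gblup) / acc_gblup
    gain2 = 100.0 * (acc_ssi - acc_blup) / acc_blup
    return gain1, gain2


_MODEL_KERNEL = {
    "GBLUP": "G", "GSSI": "G",
    "K1BLUP": "K1", "K1SSI": "K1",
    "K2BLUP": "K2", "K2SSI": "K2",
    "K3BLUP": "K3", "K3SSI": "K3",
    "KABLUP": "KA", "KASSI": "KA",
}


def _ids_hash(ids) -> str:
    return hashlib.sha1("\n".join(map(str, ids)).encode()).hexdigest()[:12]


def run_experiment(
    population: SimulatedPopulation,
    kernel_map: dict,
    models: list[str],
    scenarios: list[dict],
    n_partitions: int = 100,
    base_seed: int = 0,
    cv_folds: int = 10,
    cv_fractions: np.ndarray | None = None,
    gibbs_opts: dict | None = None,
    cv_tol: float = 1e-4,
    ssi_tol: float = 1e-5,
) -> pd.DataFrame:
    """Repeated random partitions; every model is evaluated on the same splits.

    ``kernel_map`` maps kernel keys ('G', 'K1', 'K2', 'K3') to KernelMatrix
    objects on the full population.  ``scenarios`` are dicts of
    ``build_scenario`` keyword arguments minus ``cycle_sizes`` and ``seed``.
    A 'KA' model estimates per-kernel variances by Gibbs sampling on the
    training set and averages K1..K3 with the resulting weights.
    Returns a long-format table (partition, scenario, model, rho, lambda_cv,
    n_sup, pct_sparsity, h2, n_ts, n_ps, ts_hash).
    """
    if not models or not scenarios:
        raise ValueError("models and scenarios must be non-empty")
    for m in models:
        if m not in _MODEL_KERNEL:
            raise ValueError(f"unknown model {m!r}")
    cycles, counts = np.unique(population.cycles, return_counts=True)
    cycle_sizes = dict(zip(cycles.tolist(), counts.tolist()))
    pheno = pd.Series(population.phenotype, index=population.ids)

    rows = []
    for part in range(n_partitions):
        seed = base_seed + part
        for sc_kwargs in scenarios:
            scenario = build_scenario(cycle_sizes, seed=seed, **sc_kwargs)
            ts_ids, ps_ids = partition_population(population, scenario)
            y_ts_raw = pheno.loc[ts_ids].to_numpy()
            y_ts = y_ts_raw - y_ts_raw.mean()
            y_ps = pheno.loc[ps_ids].to_numpy()
            cache: dict[str, dict] = {}
            for model in models:
                key = _MODEL_KERNEL[model]
                try:
                    ctx = cache.get(key)
                    if ctx is None:
                        ctx = _kernel_context(
                            key, kernel_map, ts_ids, ps_ids, y_ts, seed, gibbs_opts
                        )
                        cache[key] = ctx
                    rec = _evaluate_model(
                        model, ctx, y_ts, y_ps, seed, cv_folds, cv_fractions,
                        cv_tol, ssi_tol,
                    )
                except Exception as exc:  # record the failure, keep the run going
                    rec = {"rho": np.nan, "error": str(exc)}
                rec.update(
                    partition=part,
                    seed=seed,
                    scenario=scenario.label,
                    model=model,
                    n_ts=len(ts_ids),
                    n_ps=len(ps_ids),
                    ts_hash=_ids_hash(ts_ids),
                    ps_hash=_ids_hash(ps_ids),
                )
                rows.append(rec)
    return pd.DataFrame(rows)


def _kernel_context(key, kernel_map, ts_ids, ps_ids, y_ts, seed, gibbs_opts):
    """Partition the kernel and estimate variance components on the training set."""
    if key == "KA":
        for need in ("K1", "K2", "K3"):
            if need not in kernel_map:
                raise ValueError("KA models need K1, K2 and K3 in kernel_map")
        members = [kernel_map[k] for k in ("K1", "K2", "K3")]
        opts = {"n_iter": 1500, "burn_in": 500, **(gibbs_opts or {})}
        tr_parts = [kmod.partition_kernel(K, ts_ids, ps_ids)[0] for K in members]
        vc = vmod.gibbs_multi_kernel(y_ts, tr_parts, seed=seed, **opts)
        K_full = kmod.kernel_average(members, vc.kernel_variances)
        K_ts, K_ps_ts = kmod.partition_kernel(K_full, ts_ids, ps_ids)
    else:
        if key not in kernel_map:
            raise ValueError(f"kernel {key!r} missing from kernel_map")
        K_ts, K_ps_ts = kmod.partition_kernel(kernel_map[key], ts_ids, ps_ids)
        vc = vmod.reml_single_kernel(y_ts, K_ts)
    return {"K_ts": K_ts, "K_ps_ts": K_ps_ts, "vc": vc,
            "ts_ids": ts_ids, "ps_ids": ps_ids}


def _evaluate_model(model, ctx, y_ts, y_ps, seed, cv_folds, cv_fractions, cv_tol, ssi_tol):
    vc = ctx["vc"]
    lam0 = vc.lambda0
    if model.endswith("SSI"):
        cv = pmod.cross_validate_lambda(
            y_ts, ctx["K_ts"], lam0, n_folds=cv_folds, fractions=cv_fractions,
            seed=seed, tol=cv_tol,
        )
        lam = cv.selected_fraction * float(np.abs(ctx["K_ps_ts"]).max())
        hat = pmod.ssi_hat(ctx["K_ts"], ctx["K_ps_ts"], lam0, lam, tol=ssi_tol,
                           prediction_ids=ctx["ps_ids"], training_ids=ctx["ts_ids"])
        lam_cv = lam
    else:
        hat = pmod.blup_hat(ctx["K_ts"], ctx["K_ps_ts"], lam0,
                            prediction_ids=ctx["ps_ids"], training_ids=ctx["ts_ids"])
        lam_cv = 0.0
    pred = pmod.predict(hat, y_ts, model=model)
    return {
        "rho": accuracy(y_ps, pred.u_hat),
        "lambda_cv": lam_cv,
        "n_sup": pred.mean_n_sup,
        "pct_sparsity": pred.pct_sparsity,
        "h2": vc.h2,
        "error": "",
    }


def summarize_results(results: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD accuracy, sparsity and h2 per scenario x model, plus gains.

    Gain1 compares each kernel BLUP with GBLUP; Gain2 compares each SSI with
    its matching BLUP, both in percent of the baseline accuracy.
    """
    grouped = results.groupby(["scenario", "model"], sort=False)
    summary = grouped.agg(
        accuracy_mean=("rho", "mean"),
        accuracy_sd=("rho", lambda s: s.std(ddof=1)),
        lambda_cv=("lambda_cv", "mean"),
        n_sup=("n_sup", "mean"),
        pct_sparsity=("pct_sparsity", "mean"),
        h2=("h2", "mean"),
        n_ts=("n_ts", "mean"),
    ).reset_index()

    gain1, gain2 = [], []
    for _, row in summary.iterrows():
        sc = row["scenario"]
        model = row["model"]
        base_g = summary.query("scenario == @sc and model == 'GBLUP'")["accuracy_mean"]
        g1 = g2 = np.nan
        if model.endswith("BLUP") and model != "GBLUP" and len(base_g):
            g1 = 100.0 * (row["accuracy_mean"] - base_g.iloc[0]) / base_g.iloc[0]
        if model.endswith("SSI"):
            mate = model.replace("SSI", "BLUP")
            base = summary.query("scenario == @sc and model == @mate")["accuracy_mean"]
            if len(base):
                g2 = 100.0 * (row["accuracy_mean"] - base.iloc[0]) / base.iloc[0]
        gain1.append(g1)
        gain2.append(g2)
    summary["gain1_pct"] = gain1
    summary["gain2_pct"] = gain2
    return summary
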