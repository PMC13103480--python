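"""Cross-validation of genomic-prediction models and scenario tables.

Two masking strategies are supported. CV1 masks whole individuals (all their
records), mimicking prediction of entirely new individuals. CV2 masks 20% of
records independently for each trait/environment column, mimicking incomplete
phenotyping: a masked individual keeps records for its other traits, so
correlated-trait models can borrow strength. Accuracy is the Pearson
correlation between observed phenotypes and GEBVs in the validation set,
reported per validation group (trait x collection). Model comparisons use
paired t-tests over replicates: within a replicate every compared model sees
the identical mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gp_models import McmcConfig, RKHSRegressor, build_kernels

logger = logging.getLogger(__name__)

__all__ = [
    "CvScheme",
    "CvResult",
    "make_masks",
    "accuracy",
    "run_cv",
    "run_intercollection",
    "intercollection_table",
    "summarize_accuracy_table",
    "compare_models",
]


@dataclass
class CvScheme:
    strategy: str = "CV1"
    mask_fraction: float = 0.2
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("CV1", "CV2"):
            raise ValueError("strategy must be 'CV1' or 'CV2'")
        if not (0 < self.mask_fraction < 1):
            raise ValueError("mask_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class CvResult:
    accuracies: pd.DataFrame  # replicate, model, trait, collection, accuracy, n
    summary: pd.DataFrame  # model x group mean/sd
    comparisons: pd.DataFrame  # model_a, model_b, t, p
    scheme: CvScheme
    replicate_means: pd.DataFrame = field(default=None)


def make_masks(scheme: CvScheme, records: pd.DataFrame):
    """Per-replicate boolean mask arrays (True = phenotype hidden).

    Deterministic per (seed, replicate); CV1 samples individuals, CV2 samples
    records independently within each (trait, collection) cell.
    """
    df = records.records if hasattr(records, "records") else records
    masks = []
    for rep in range(scheme.n_replicates):
        rng = np.random.default_rng([scheme.seed, rep])
        mask = np.zeros(len(df), dtype=bool)
        if scheme.strategy == "CV1":
            individuals = df["individual_id"].unique()
            k = int(round(scheme.mask_fraction * len(individuals)))
            if k == 0:
                raise ValueError("mask fraction yields zero masked individuals")
            chosen = rng.choice(individuals, size=k, replace=False)
            mask = df["individual_id"].isin(chosen).to_numpy()
        else:  # CV2
            for _, grp in df.groupby(["trait", "collection"], sort=True):
                k = int(round(scheme.mask_fraction * len(grp)))
                if k == 0:
                    raise ValueError("mask fraction yields zero masked records")
                rows = rng.choice(grp.index.to_numpy(), size=k, replace=False)
                mask[rows] = True
        masks.append(mask)
    return masks


def accuracy(observed, gebv) -> float:
    """Pearson correlation between observed phenotypes and GEBVs."""
    observed = np.asarray(observed, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if len(observed) != len(gebv):
        raise ValueError("length mismatch")
    if len(observed) < 3:
        raise ValueError("accuracy needs at least 3 pairs")
    if observed.std() == 0 or gebv.std() == 0:
        logger.warning("zero variance in accuracy inputs; reporting NaN")
        return float("nan")
    return float(stats.pearsonr(observed, gebv)[0])


def _group_accuracies(df, y, gebv, mask, rep, model):
    rows = []
    masked = df[mask]
    for (trait, coll), grp in masked.groupby(["trait", "collection"], sort=True):
        idx = grp.index.to_numpy()
        if len(idx) < 3:
            continue
        rows.append(
            dict(
                replicate=rep,
                model=model,
                trait=trait,
                collection=coll,
                accuracy=accuracy(y[idx], gebv[idx]),
                n_validation=len(idx),
            )
        )
    return rows


def run_cv(records, grm, models, scheme: CvScheme, mcmc: McmcConfig | None = None) -> CvResult:
    """Replicate CV of one or more models with shared masks.

    Kernels (and their eigendecompositions) are built once per model and
    reused across replicates; only the mask changes. A failed model fit flags
    the replicate for that model and the remaining models proceed.
    """
    df = (records.records if hasattr(records, "records") else records).reset_index(
        drop=True
    )
    y = df["value"].to_numpy(dtype=float)
    mcmc = mcmc or McmcConfig()
    kernel_sets = {m: build_kernels(m, df, grm) for m in models}
    masks = make_masks(scheme, df)
    rows = []
    for rep, mask in enumerate(masks):
        y_rep = y.copy()
        y_rep[mask] = np.nan
        for mi, model in enumerate(models):
            seed = (mcmc.seed * 100_003 + rep * 131 + mi) % (2**31)
            est = RKHSRegressor(
                n_burn_in=mcmc.n_burn_in,
                n_sampling=mcmc.n_sampling,
                thin=mcmc.thin,
                prior_df=mcmc.prior_df,
                prior_r2=mcmc.prior_r2,
                seed=seed,
            )
            try:
                est.fit(kernel_sets[model], y_rep)
            except Exception as exc:  # noqa: BLE001 - replicate flagged, not fatal
                logger.warning("replicate %d model %s failed: %s", rep, model, exc)
                rows.append(
                    dict(
                        replicate=rep,
                        model=model,
                        trait=None,
                        collection=None,
                        accuracy=np.nan,
                        n_validation=0,
                    )
                )
                continue
            rows.extend(_group_accuracies(df, y, est.gebv_, mask, rep, model))
    acc = pd.DataFrame(rows)
    summary = (
        acc.groupby(["model", "trait", "collection"])["accuracy"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    rep_means = (
        acc.groupby(["model", "replicate"])["accuracy"].mean().unstack(level=0)
    )
    comp_rows = []
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            t, p = compare_models(rep_means[a].to_numpy(), rep_means[b].to_numpy())
            comp_rows.append(dict(model_a=a, model_b=b, t=t, p=p))
    comparisons = pd.DataFrame(comp_rows)
    return CvResult(
        accuracies=acc,
        summary=summary,
        comparisons=comparisons,
        scheme=scheme,
        replicate_means=rep_means,
    )


def run_intercollection(
    records,
    grm,
    reference_collections,
    validation_collections,
    model: str = "Single",
    trait=None,
    mcmc: McmcConfig | None = None,
) -> pd.DataFrame:
    """Train on reference collections, predict every validation individual.

    Validation records enter the model with hidden phenotypes (the mechanism
    that produces their GEBVs) and accuracy is reported per validation
    collection.
    """
    reference_collections = list(reference_collections)
    validation_collections = list(validation_collections)
    overlap = set(reference_collections) & set(validation_collections)
    if overlap:
        raise ValueError(
            f"validation collections {sorted(overlap)} overlap the reference; "
            "use within-collection CV for the diagonal"
        )
    df = (records.records if hasattr(records, "records") else records).reset_index(
        drop=True
    )
    if trait is not None:
        df = df[df["trait"] == trait].reset_index(drop=True)
    wanted = reference_collections + validation_collections
    df = df[df["collection"].isin(wanted)].reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    mask = df["collection"].isin(validation_collections).to_numpy()
    y_train = y.copy()
    y_train[mask] = np.nan
    mcmc = mcmc or McmcConfig()
    kernels = build_kernels(model, df, grm)
    est = RKHSRegressor(
        n_burn_in=mcmc.n_burn_in,
        n_sampling=mcmc.n_sampling,
        thin=mcmc.thin,
        prior_df=mcmc.prior_df,
        prior_r2=mcmc.prior_r2,
        seed=mcmc.seed,
    ).fit(kernels, y_train)
    rows = []
    for coll in validation_collections:
        idx = np.where((df["collection"] == coll).to_numpy())[0]
        rows.append(
            dict(
                reference="+".join(reference_collections),
                validation=coll,
                accuracy=accuracy(y[idx], est.gebv_[idx]),
                n_validation=len(idx),
            )
        )
    return pd.DataFrame(rows)


def intercollection_table(
    records,
    grm,
    collections,
    model: str = "Single",
    trait=None,
    mcmc: McmcConfig | None = None,
) -> pd.DataFrame:
    """Single-reference cross-prediction accuracy for every ordered pair of
    collections (off-diagonal cells of the reference x validation table)."""
    parts = []
    for ref in collections:
        others = [c for c in collections if c != ref]
        parts.append(
            run_intercollection(
                records, grm, [ref], others, model=model, trait=trait, mcmc=mcmc
            )
        )
    return pd.concat(parts, ignore_index=True)


def summarize_accuracy_table(table: pd.DataFrame) -> pd.Series:
    """Per-model column means of a per-trait accuracy table, 2 decimals."""
    if table.shape[1] < 1:
        raise ValueError("need at least one column")
    numeric = table.select_dtypes("number")
    return numeric.mean(axis=0).round(2)


def compare_models(acc_a, acc_b):
    """Paired two-sided t-test on per-replicate accuracy differences."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired comparison needs equal-length vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 paired replicates")
    diff = a - b
    if np.allclose(diff.std(), 0):
        if np.allclose(diff.mean(), 0):
            return 0.0, 1.0
        logger.warning("constant nonzero difference; p reported as 0")
        return float(np.inf * np.sign(diff.mean())), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
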