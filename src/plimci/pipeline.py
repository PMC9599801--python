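"""End-to-end study orchestration: synthetic cohort -> preprocessing ->
band-wise PLI connectivity -> group statistics -> classification ->
MoCA correlation, emitted as a bundle of CSV/JSON files.

Outputs of :func:`run_study` (all deterministic given the config seed, and
byte-identical across reruns):

* ``cohort.csv``             subject table incl. ground-truth alpha PLI
* ``table1_cohort.csv``      clinical characteristics with group tests
* ``global_pli_by_band.csv`` per-band global PLI group comparison
* ``alpha_pairs.csv``        the eight named electrode pairs, alpha band
* ``mean_alpha_matrix_<G>.csv`` group-mean alpha connectivity matrices
* ``classifier_report.json`` pooled CV metrics + empirical chance level
* ``roc_points.csv``         pooled-CV ROC curve
* ``moca_correlation.csv``   MoCA vs global alpha PLI, per group
* ``run_log.json``           every parameter and seed of the run
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import FeatureMatrix, cross_validate, empirical_chance_level
from .montage import NAMED_PAIRS
from .pli import BANDS, connectivity_matrix, extract_pairs, global_pli
from .preprocess import PreprocessParams, preprocess
from .stats import (
    PRINTED_TABLE1,
    chi_square_2x2,
    independent_t_test,
    independent_t_test_from_samples,
    normality_check,
    pearson_correlation,
    rank_sum_test,
)
from .synth import CohortSpec, RecordingSpec, generate_cohort

FLOAT_FMT = "%.10g"


@dataclass
class StudyConfig:
    """One self-contained study: synthesis, preprocessing, features, seed."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    feature_set: str = "pairs8+global"  # or "global", "allpairs"
    n_folds: int = 10
    n_permutations: int = 5000
    chance_percentile: float = 95.0
    seed: int = 0
    out_dir: str = "results/study"
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.feature_set not in ("global", "pairs8+global", "allpairs"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")


def config_from_toml(path: str | Path) -> StudyConfig:
    """Build a config from a flat TOML file; unknown keys are rejected."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    rec_keys = {f: raw.pop(f) for f in (
        "n_channels", "sampling_rate", "duration", "noise_sd", "noise_color",
        "posterior_alpha_gain", "include_aux",
    ) if f in raw}
    if "alpha_coupling" in raw:
        from .synth import DEFAULT_COUPLING

        coupling = dict(DEFAULT_COUPLING)
        coupling["alpha"] = raw.pop("alpha_coupling")
        rec_keys["coupling_strength"] = coupling
    cohort_keys = {f: raw.pop(f) for f in (
        "n_per_group", "group_effect", "subject_coupling_sd",
    ) if f in raw}
    pre_keys = {f: raw.pop(f) for f in (
        "bandpass_low", "bandpass_high", "notch_low", "notch_high",
        "downsample_to", "epoch_length", "reject_threshold", "rereference",
    ) if f in raw}
    cfg_keys = {f: raw.pop(f) for f in (
        "feature_set", "n_folds", "n_permutations", "chance_percentile",
        "seed", "out_dir", "make_figures",
    ) if f in raw}
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    cohort = CohortSpec(
        recording=RecordingSpec(**rec_keys),
        seed=cfg_keys.get("seed", 0),
        **cohort_keys,
    )
    return StudyConfig(cohort=cohort, preprocess=PreprocessParams(**pre_keys), **cfg_keys)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def compute_subject_features(
    recordings: dict, params: PreprocessParams
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Preprocess every recording and compute per-band global PLI plus the
    named alpha pair values; returns the feature table and the per-subject
    alpha connectivity matrices."""
    rows = []
    alpha_matrices: dict[str, dict] = {}
    for sid in sorted(recordings):
        es = preprocess(recordings[sid], params)
        row: dict = {"subject_id": sid, "n_epochs_kept": es.n_epochs}
        for name, band in BANDS.items():
            cm = connectivity_matrix(es, band)
            row[f"global_pli_{name}"] = global_pli(cm)
            if name == "alpha":
                alpha_matrices[sid] = cm
                have = set(cm.channel_labels)
                for a, b in NAMED_PAIRS:
                    if a in have and b in have:
                        row[f"pli_{a}_{b}"] = cm.pair(a, b)
        rows.append(row)
    return pd.DataFrame(rows), alpha_matrices


def _table1(table: pd.DataFrame) -> pd.DataFrame:
    """Clinical characteristics of the synthetic cohort with group tests."""
    mci = table[table.group == "MCI"]
    nc = table[table.group == "NC"]
    rows = []
    counts = [
        [int((mci.sex == "M").sum()), int((mci.sex == "F").sum())],
        [int((nc.sex == "M").sum()), int((nc.sex == "F").sum())],
    ]
    res = chi_square_2x2(counts)
    rows.append({
        "characteristic": "gender_mf",
        "MCI": f"{counts[0][0]}/{counts[0][1]}", "NC": f"{counts[1][0]}/{counts[1][1]}",
        "test": "chi_square", "statistic": res.statistic, "p": res.p_value,
    })
    for col in ("age", "education_years", "moca", "t2dm_duration_years"):
        x, y = mci[col].to_numpy(), nc[col].to_numpy()
        normal = normality_check(x)[0] and normality_check(y)[0]
        res = (independent_t_test_from_samples(x, y) if normal
               else rank_sum_test(x, y, method="asymptotic"))
        rows.append({
            "characteristic": col,
            "MCI": f"{x.mean():.2f} +/- {x.std(ddof=1):.2f}",
            "NC": f"{y.mean():.2f} +/- {y.std(ddof=1):.2f}",
            "test": "t" if normal else "rank_sum",
            "statistic": res.statistic, "p": res.p_value,
        })
    return pd.DataFrame(rows)


def build_features(
    features: pd.DataFrame,
    table: pd.DataFrame,
    feature_set: str,
    alpha_matrices: dict | None = None,
) -> FeatureMatrix:
    merged = table[["subject_id", "group"]].merge(features, on="subject_id")
    merged = merged.sort_values("subject_id").reset_index(drop=True)
    if feature_set == "global":
        cols = ["global_pli_alpha"]
    elif feature_set == "pairs8+global":
        cols = ["global_pli_alpha"] + [c for c in merged.columns if c.startswith("pli_")]
    else:  # allpairs: every upper-triangle alpha pair
        if alpha_matrices is None:
            raise ValueError("allpairs feature set requires the alpha matrices")
        labels = next(iter(alpha_matrices.values())).channel_labels
        iu, ju = np.triu_indices(len(labels), k=1)
        X = np.stack([
            alpha_matrices[sid].values[iu, ju] for sid in merged.subject_id
        ])
        names = [f"allpair_{labels[i]}_{labels[j]}" for i, j in zip(iu, ju)]
        return FeatureMatrix(X=X, feature_names=names,
                             labels=merged["group"].to_numpy())
    return FeatureMatrix(
        X=merged[cols].to_numpy(),
        feature_names=cols,
        labels=merged["group"].to_numpy(),
    )


def run_study(cfg: StudyConfig) -> dict:
    """Run the whole study and write the report bundle to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_spec = replace(cfg.cohort, seed=cfg.seed)

    table, recordings = generate_cohort(cohort_spec)
    _write_csv(table, out / "cohort.csv")

    features, alpha_matrices = compute_subject_features(recordings, cfg.preprocess)
    _write_csv(features, out / "subject_features.csv")

    table1 = _table1(table)
    _write_csv(table1, out / "table1_cohort.csv")

    merged = table.merge(features, on="subject_id")
    mci = merged[merged.group == "MCI"]
    nc = merged[merged.group == "NC"]

    band_rows = []
    for name in BANDS:
        col = f"global_pli_{name}"
        res = rank_sum_test(mci[col], nc[col], method="asymptotic")
        band_rows.append({
            "band": name,
            "mean_MCI": mci[col].mean(), "sd_MCI": mci[col].std(ddof=1),
            "mean_NC": nc[col].mean(), "sd_NC": nc[col].std(ddof=1),
            "rank_sum_z": res.statistic, "p": res.p_value,
        })
    band_df = pd.DataFrame(band_rows)
    _write_csv(band_df, out / "global_pli_by_band.csv")

    pair_rows = []
    for a, b in NAMED_PAIRS:
        col = f"pli_{a}_{b}"
        if col not in merged.columns:
            continue
        res = rank_sum_test(mci[col], nc[col], method="asymptotic")
        pair_rows.append({
            "pair": f"{a}-{b}",
            "mean_MCI": mci[col].mean(), "sd_MCI": mci[col].std(ddof=1),
            "mean_NC": nc[col].mean(), "sd_NC": nc[col].std(ddof=1),
            "rank_sum_z": res.statistic, "p": res.p_value,
        })
    pairs_df = pd.DataFrame(pair_rows)
    _write_csv(pairs_df, out / "alpha_pairs.csv")

    labels = next(iter(alpha_matrices.values())).channel_labels
    for group, sub in (("MCI", mci), ("NC", nc)):
        mean_mat = np.mean([alpha_matrices[s].values for s in sub.subject_id], axis=0)
        mat_df = pd.DataFrame(mean_mat, index=labels, columns=labels)
        mat_df.to_csv(out / f"mean_alpha_matrix_{group}.csv", float_format=FLOAT_FMT)

    fm = build_features(features, table, cfg.feature_set, alpha_matrices)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    cv_seed = int(rng.integers(0, 2**31 - 1))
    report = cross_validate(fm, k=cfg.n_folds, seed=cv_seed)
    report.empirical_chance_level = empirical_chance_level(
        fm, n_permutations=cfg.n_permutations, percentile=cfg.chance_percentile,
        seed=int(rng.integers(0, 2**31 - 1)), k=cfg.n_folds,
    )
    report.n_permutations = cfg.n_permutations
    (out / "classifier_report.json").write_text(
        json.dumps(report.as_dict(), indent=2, sort_keys=True) + "\n"
    )
    _write_csv(pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]),
               out / "roc_points.csv")

    corr_rows = []
    for group, sub in (("MCI", mci), ("NC", nc)):
        res = pearson_correlation(sub["global_pli_alpha"], sub["moca"])
        corr_rows.append({"group": group, "r": res.statistic, "p": res.p_value,
                          "n": res.n})
    corr_df = pd.DataFrame(corr_rows)
    _write_csv(corr_df, out / "moca_correlation.csv")

    if cfg.make_figures:
        _make_figures(out, band_df, report, alpha_matrices, merged)

    log = {
        "package_version": __version__,
        "seed": cfg.seed,
        "cv_seed": cv_seed,
        "feature_set": cfg.feature_set,
        "n_folds": cfg.n_folds,
        "n_permutations": cfg.n_permutations,
        "chance_percentile": cfg.chance_percentile,
        "preprocess": asdict(cfg.preprocess),
        "cohort": {
            "n_per_group": cohort_spec.n_per_group,
            "group_effect": cohort_spec.group_effect,
            "subject_coupling_sd": cohort_spec.subject_coupling_sd,
            "recording": {
                "n_channels": cohort_spec.recording.n_channels,
                "sampling_rate": cohort_spec.recording.sampling_rate,
                "duration": cohort_spec.recording.duration,
                "coupling_strength": cohort_spec.recording.coupling_strength,
                "noise_sd": cohort_spec.recording.noise_sd,
                "noise_color": cohort_spec.recording.noise_color,
                "posterior_alpha_gain": cohort_spec.recording.posterior_alpha_gain,
                "include_aux": cohort_spec.recording.include_aux,
            },
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {
        "cohort": table, "features": features, "table1": table1,
        "global_pli_by_band": band_df, "alpha_pairs": pairs_df,
        "classifier_report": report, "moca_correlation": corr_df,
        "out_dir": str(out),
    }


def _make_figures(out: Path, band_df, report, alpha_matrices, merged) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "--", color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"Pooled cross-validated ROC (AUC = {report.auc:.3f})")
    fig.savefig(out / "roc_curve.png", dpi=120)
    plt.close(fig)

    for group in ("MCI", "NC"):
        subs = merged[merged.group == group].subject_id
        mean_mat = np.mean([alpha_matrices[s].values for s in subs], axis=0)
        fig, ax = plt.subplots()
        im = ax.imshow(mean_mat, vmin=0, vmax=max(0.5, mean_mat.max()), cmap="jet")
        fig.colorbar(im, ax=ax, label="PLI")
        ax.set_title(f"Group-mean alpha PLI: {group}")
        fig.savefig(out / f"mean_alpha_matrix_{group}.png", dpi=120)
        plt.close(fig)


def validate_table1() -> dict:
    """Recompute the reproducible clinical-table statistics from the printed
    group summaries and report agreement at 3 decimals.

    The age and MoCA t-values are known not to be recoverable from the
    rounded printed summaries (they recompute to -0.509 and -12.42); they
    are reported as informational, not checked.
    """
    t1 = PRINTED_TABLE1
    n = t1["n_per_group"]
    out: dict = {"checks": {}, "informational": {}}

    res = chi_square_2x2([t1["gender_mf"]["MCI"], t1["gender_mf"]["NC"]])
    out["checks"]["gender_chi2"] = {
        "computed": round(res.statistic, 3), "printed": t1["gender_mf"]["chi2"],
        "computed_p": round(res.p_value, 3), "printed_p": t1["gender_mf"]["p"],
    }
    for key, label in (("education_years", "education_t"),
                       ("t2dm_duration_years", "duration_t")):
        (m1, s1), (m2, s2) = t1[key]["MCI"], t1[key]["NC"]
        res = independent_t_test(m1, s1, n, m2, s2, n)
        out["checks"][label] = {
            "computed": round(res.statistic, 3), "printed": t1[key]["t"],
            "computed_p": round(res.p_value, 3), "printed_p": t1[key]["p"],
        }
    for key, label in (("age_years", "age_t"), ("moca_score", "moca_t")):
        (m1, s1), (m2, s2) = t1[key]["MCI"], t1[key]["NC"]
        res = independent_t_test(m1, s1, n, m2, s2, n)
        out["informational"][label] = {
            "computed": round(res.statistic, 3), "printed": t1[key]["t"],
            "note": "not recoverable from rounded summaries; excluded from checks",
        }
    out["all_match_3dp"] = all(
        c["computed"] == c["printed"] and c.get("computed_p") == c.get("printed_p")
        for c in out["checks"].values()
    )
    return out
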