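"""End-to-end orchestration: simulate → preprocess → spectrogram → coupling →
group statistics → (optionally) the nested-CV SVM protocol.

A single declarative :class:`PipelineConfig` drives the run; the returned
:class:`RunReport` bundles every table a report would cite, stamped with the
seed and a hash of the configuration for provenance.  Deterministic given
the seed: the cohort seed fans out to per-subject child seeds inside the
generator, so processing order cannot change results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coupling import median_split, subject_coupling
from .features import build_subject_features, eeg_feature_matrix
from .groupstats import (
    Contrast,
    feature_neuropsych_corr,
    independent_t_d,
    mixed_anova,
    posthoc_pairwise,
)
from .ml import nested_cv_classify, nested_cv_regress
from .preprocess import (
    DEFAULT_RT_WINDOW_MS,
    bandpass_fir,
    baseline_correct,
    behavioral_summary,
    exclude_trials,
    rereference_average,
)
from .simulate import (
    CONDITIONS,
    GROUPS,
    EpochedRecording,
    SimulationParams,
    simulate_cohort,
)
from .timefreq import AlphaROI, prestimulus_alpha_power


@dataclass
class PipelineConfig:
    simulation: SimulationParams = field(default_factory=SimulationParams)
    bandpass: tuple[float, float] = (1.0, 30.0)
    baseline_window: tuple[float, float] = (-2000.0, 0.0)
    rt_window_ms: float = DEFAULT_RT_WINDOW_MS
    outlier_sd: float | None = 2.0
    roi: AlphaROI = field(default_factory=AlphaROI)
    median_scope: str = "condition"  # or "global"
    run_ml: bool = False
    ml_k: int = 10
    ml_reps: int = 100
    ml_max_subset_size: int = 2
    ml_c_grid: tuple[float, ...] | None = None
    ml_g_grid: tuple[float, ...] | None = None
    ml_leak_rescale: bool = False
    ml_regression_targets: tuple[str, ...] = ()
    outdir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("simulation"), dict):
            d["simulation"] = SimulationParams.from_dict(d["simulation"])
        if isinstance(d.get("roi"), dict):
            roi = dict(d["roi"])
            if isinstance(roi.get("electrodes"), list):
                roi["electrodes"] = tuple(roi["electrodes"])
            d["roi"] = AlphaROI(**roi)
        for key in ("bandpass", "baseline_window", "ml_regression_targets",
                    "ml_c_grid", "ml_g_grid"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config: dict
    config_hash: str
    seed: int
    version: str
    behavioral: pd.DataFrame  # per subject
    coupling: pd.DataFrame  # per subject × condition
    features: pd.DataFrame  # per subject, 15 features
    neuropsych: pd.DataFrame
    anovas: dict[str, pd.DataFrame]
    contrasts: pd.DataFrame
    group_tests: pd.DataFrame
    neuro_correlations: pd.DataFrame
    ml_classification: dict | None = None
    ml_regression: dict | None = None
    exclusion_log: pd.DataFrame | None = None

    _SECTIONS = (
        "behavioral", "coupling", "features", "neuropsych",
        "contrasts", "group_tests", "neuro_correlations",
    )


def process_subject(
    rec: EpochedRecording, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess one subject and return (trial table with alpha power and
    speed bins, one-row behavioral summary)."""
    rec = rereference_average(rec)
    rec = bandpass_fir(rec, *config.bandpass)
    rec = baseline_correct(rec, config.baseline_window)
    table = exclude_trials(
        rec.trial_table,
        rt_window_ms=config.rt_window_ms,
        outlier_sd=config.outlier_sd,
    )
    alpha = prestimulus_alpha_power(rec, config.roi)
    table = table.assign(alpha_power=alpha)
    table = median_split(table, scope=config.median_scope)
    behav = behavioral_summary(table)
    return table, behav


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and bundle the results.

    Stage errors are re-raised with the stage and subject attached.
    """
    params = dataclasses.replace(config.simulation, seed=config.seed)
    recordings, neuropsych = simulate_cohort(params)

    behav_rows = {}
    coupling_frames = []
    excl_rows = []
    for rec in recordings:
        try:
            table, behav = process_subject(rec, config)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"stage=process_subject subject={rec.subject_id}: {exc}"
            ) from exc
        behav_rows[rec.subject_id] = {"group": rec.group, **behav.iloc[0].to_dict()}
        coupling_frames.append(
            subject_coupling(table, subject=rec.subject_id, group=rec.group)
        )
        excl_rows.append(
            {
                "subject": rec.subject_id,
                "group": rec.group,
                "n_trials": len(table),
                "n_invalid": int((~table["valid"]).sum()),
                "n_outlier": int(table["outlier"].sum()),
                "n_incorrect": int((~table["correct"]).sum()),
                "n_included": int(table["included"].sum()),
            }
        )
    behavioral = pd.DataFrame.from_dict(behav_rows, orient="index")
    behavioral.index.name = "subject"
    coupling = pd.concat(coupling_frames, ignore_index=True)
    features = build_subject_features(behavioral, coupling)
    exclusion_log = pd.DataFrame(excl_rows).set_index("subject")

    # --- group statistics -------------------------------------------------
    anovas: dict[str, pd.DataFrame] = {}
    long_behav = []
    for subj, row in behavioral.iterrows():
        for cond in CONDITIONS:
            long_behav.append(
                {
                    "subject": subj,
                    "group": row["group"],
                    "congruency": cond,
                    "rt": row[f"RT_{cond}"],
                    "er": row[f"ER_{cond}"],
                }
            )
    long_behav = pd.DataFrame(long_behav)
    anovas["rt"] = mixed_anova(long_behav, "rt", "subject", "group", ["congruency"])
    anovas["er"] = mixed_anova(long_behav, "er", "subject", "group", ["congruency"])

    long_alpha = []
    for _, crow in coupling.iterrows():
        for speed in ("fast", "slow"):
            long_alpha.append(
                {
                    "subject": crow["subject"],
                    "group": crow["group"],
                    "congruency": crow["condition"],
                    "speed": speed,
                    "alpha": crow[f"alpha_{speed}"],
                }
            )
    long_alpha = pd.DataFrame(long_alpha)
    anovas["alpha"] = mixed_anova(
        long_alpha, "alpha", "subject", "group", ["speed", "congruency"]
    )

    long_z = coupling.rename(columns={"condition": "congruency"})
    anovas["z"] = mixed_anova(long_z, "z", "subject", "group", ["congruency"])

    # simple effects of speed within each group (one Bonferroni family)
    fam = []
    for g in GROUPS:
        sub = long_alpha[long_alpha["group"] == g]
        cell = sub.pivot_table(index="subject", columns="speed", values="alpha")
        fam.append(
            Contrast(
                name=f"{g}: slow vs fast",
                x=cell["slow"].to_numpy(),
                y=cell["fast"].to_numpy(),
                paired=True,
            )
        )
    contrasts = posthoc_pairwise(fam)

    # between-group tests on the coupling summaries (mean over conditions)
    subj_mean = coupling.groupby(["subject", "group"], as_index=False).agg(
        alpha_diff=("alpha_diff", "mean"), z=("z", "mean")
    )
    test_rows = []
    for name in ("alpha_diff", "z"):
        hc = subj_mean.loc[subj_mean["group"] == "HC", name].to_numpy()
        mci = subj_mean.loc[subj_mean["group"] == "MCI", name].to_numpy()
        test_rows.append({"measure": name, **independent_t_d(hc, mci)})
    group_tests = pd.DataFrame(test_rows)

    neuro_correlations = pd.concat(
        [
            feature_neuropsych_corr(
                eeg_feature_matrix(features).assign(group=features["group"]),
                neuropsych,
                g,
            )
            for g in GROUPS
        ],
        ignore_index=True,
    )

    report = RunReport(
        config=config.to_dict(),
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        behavioral=behavioral,
        coupling=coupling,
        features=features,
        neuropsych=neuropsych,
        anovas=anovas,
        contrasts=contrasts,
        group_tests=group_tests,
        neuro_correlations=neuro_correlations,
        exclusion_log=exclusion_log,
    )

    if config.run_ml:
        kw: dict = dict(
            k=config.ml_k,
            reps=config.ml_reps,
            max_subset_size=config.ml_max_subset_size,
            seed=config.seed,
            leak_rescale=config.ml_leak_rescale,
        )
        if config.ml_c_grid:
            kw["c_grid"] = config.ml_c_grid
        if config.ml_g_grid:
            kw["g_grid"] = config.ml_g_grid
        Xc = features.drop(columns="group")
        ycls = features["group"].to_numpy()
        report.ml_classification = nested_cv_classify(Xc, ycls, **kw).to_dict()
        reg_reports = {}
        for target in config.ml_regression_targets:
            tvec = neuropsych.loc[features.index, target].to_numpy(dtype=float)
            reg_reports[target] = nested_cv_regress(
                eeg_feature_matrix(features), tvec, **kw
            ).to_dict()
        report.ml_regression = reg_reports or None

    if config.outdir:
        export_report(report, config.outdir)
    return report


def simulate_z_table(
    rho_by_group: dict[str, float],
    n_per_group: int = 28,
    trials_per_condition: int = 60,
    seed: int = 0,
    params: SimulationParams | None = None,
) -> pd.DataFrame:
    """Trial-level shortcut for calibration studies: per-subject Fisher-z
    coupling computed from the generator's true alpha amplitudes, bypassing
    EEG synthesis and power estimation.

    The copula, trial counts and RT distributions are identical to the full
    pipeline; only the measurement stage (which attenuates but cannot create
    coupling) is skipped.  Used for Monte-Carlo calibration of the group
    inference, where thousands of cohorts are needed.  Returns a long frame
    (subject, group, congruency, rho, z).
    """
    from .coupling import fisher_z, spearman_rho
    from .simulate import simulate_trial_pairs

    params = params or SimulationParams()
    root = np.random.SeedSequence(seed)
    rows = []
    i = 0
    for group in GROUPS:
        rho_g = rho_by_group[group]
        for _ in range(n_per_group):
            rng = np.random.default_rng(root.spawn(1)[0])
            subj = f"S{i:03d}"
            i += 1
            for cond in CONDITIONS:
                a, rt = simulate_trial_pairs(
                    rho_g,
                    trials_per_condition,
                    rng,
                    rt_mean=params.rt_mean[cond],
                    rt_sd=params.rt_sd[cond],
                    amp_mu=params.alpha_amp_mu,
                    amp_sigma=params.alpha_amp_sigma,
                    rt_min=params.rt_min,
                )
                r = spearman_rho(a**2, rt)
                rows.append(
                    {
                        "subject": subj,
                        "group": group,
                        "congruency": cond,
                        "rho": r,
                        "z": fisher_z(r, clamp=1 - 1e-7),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _df_to_json(df: pd.DataFrame) -> dict:
    if df.index.name is not None:
        df = df.reset_index()
    return json.loads(df.to_json(orient="split", index=False))


def _df_from_json(d: dict, index: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(d["data"], columns=d["columns"])
    if index and index in df.columns:
        df = df.set_index(index)
    return df


def export_report(
    report: RunReport, outdir: str | Path, formats: tuple[str, ...] = ("csv", "json")
) -> Path:
    """Write tidy CSVs and a machine-readable JSON bundle.

    Raises if a required section is missing (``None``).
    """
    missing = [s for s in RunReport._SECTIONS if getattr(report, s) is None]
    if missing:
        raise ValueError(f"report missing sections: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "csv" in formats:
        report.behavioral.to_csv(outdir / "behavioral.csv")
        report.coupling.to_csv(outdir / "coupling.csv", index=False)
        report.features.to_csv(outdir / "features.csv")
        report.neuropsych.to_csv(outdir / "neuropsych.csv")
        report.contrasts.to_csv(outdir / "contrasts.csv", index=False)
        report.group_tests.to_csv(outdir / "group_tests.csv", index=False)
        report.neuro_correlations.to_csv(outdir / "neuro_correlations.csv", index=False)
        for name, table in report.anovas.items():
            table.to_csv(outdir / f"anova_{name}.csv", index=False)
        if report.exclusion_log is not None:
            report.exclusion_log.to_csv(outdir / "exclusion_log.csv")
    if "json" in formats:
        payload = {
            "schema_version": _SCHEMA_VERSION,
            "config": report.config,
            "config_hash": report.config_hash,
            "seed": report.seed,
            "version": report.version,
            "behavioral": _df_to_json(report.behavioral),
            "coupling": _df_to_json(report.coupling),
            "features": _df_to_json(report.features),
            "neuropsych": _df_to_json(report.neuropsych),
            "anovas": {k: _df_to_json(v) for k, v in report.anovas.items()},
            "contrasts": _df_to_json(report.contrasts),
            "group_tests": _df_to_json(report.group_tests),
            "neuro_correlations": _df_to_json(report.neuro_correlations),
            "ml_classification": report.ml_classification,
            "ml_regression": report.ml_regression,
            "exclusion_log": (
                _df_to_json(report.exclusion_log)
                if report.exclusion_log is not None
                else None
            ),
        }
        (outdir / "report.json").write_text(json.dumps(payload))
    return outdir


def load_report(path: str | Path) -> RunReport:
    """Re-read a JSON report bundle written by :func:`export_report`."""
    path = Path(path)
    if path.is_dir():
        path = path / "report.json"
    payload = json.loads(path.read_text())
    return RunReport(
        config=payload["config"],
        config_hash=payload["config_hash"],
        seed=payload["seed"],
        version=payload["version"],
        behavioral=_df_from_json(payload["behavioral"], index="subject"),
        coupling=_df_from_json(payload["coupling"]),
        features=_df_from_json(payload["features"], index="subject"),
        neuropsych=_df_from_json(payload["neuropsych"], index="subject"),
        anovas={k: _df_from_json(v) for k, v in payload["anovas"].items()},
        contrasts=_df_from_json(payload["contrasts"]),
        group_tests=_df_from_json(payload["group_tests"]),
        neuro_correlations=_df_from_json(payload["neuro_correlations"]),
        ml_classification=payload.get("ml_classification"),
        ml_regression=payload.get("ml_regression"),
        exclusion_log=(
            _df_from_json(payload["exclusion_log"], index="subject")
            if payload.get("exclusion_log") is not None
            else None
        ),
    )
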