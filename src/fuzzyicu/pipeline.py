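"""Stage orchestration: simulate -> domains -> normalize -> cluster -> stays -> report.

Each stage reads its upstream artifacts from the working directory, writes its
own outputs (CSV tables, JSON domain/model artifacts, PNG charts) and appends a
manifest entry with input checksums, the seed and the package version, so a
re-run with unchanged inputs is byte-identical for all CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import KModesModel, assign_full, elbow_select, kmodes_fit
from .domains import (
    MONITORING_LABELS,
    THERAPY_LABELS,
    domain_from_observations,
    load_domains,
    plot_domain,
    save_domains,
)
from .patterns import build_monitoring_records, build_therapy_records, dedup, normalize_records
from .simulate import DEFAULT_DRUG_VOCABULARY, DEFAULT_MONITORING_SCHEMA, SimConfig, simulate_cohort
from .stays import (
    HOUR_COLUMNS,
    build_stay_table,
    chi_square,
    contingency,
    extract_stay_window,
    nabtcl_summary,
    plot_fuzzified_ribbon,
    stay_chart,
    subset_frequencies,
)

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_domains",
    "run_normalize",
    "run_cluster",
    "run_stays",
    "run_report",
    "run_all",
    "run_stage",
    "STAGES",
]

log = logging.getLogger("fuzzyicu")


@dataclass
class PipelineConfig:
    """All pipeline knobs; loadable from YAML with defaults for anything unset."""

    workdir: Path = Path("out")
    seed: int = 0
    n_patients: int = 200
    trim_coverage: float = 0.95
    therapy_trim_mode: str = "upper"
    monitoring_trim_mode: str = "central"
    overlap_rule: str = "half_sd"
    therapy_k: int | str = 4
    monitoring_k: int | str = 7
    k_max: int = 25
    n_init: int = 5
    max_iter: int = 100
    grace_days: int = 0
    aggregator: str = "median"
    charts: bool = True
    min_obs_for_domain: int = 10
    planted_k: int | None = None

    def __post_init__(self):
        self.workdir = Path(self.workdir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    # --- artifact paths ---
    def path(self, *parts: str) -> Path:
        return self.workdir.joinpath(*parts)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact {path} (run the '{produced_by}' stage first)")
    return path


def _write_manifest(cfg: PipelineConfig, stage: str, inputs: list[Path], outputs: list[Path], params: dict) -> None:
    manifest_path = cfg.path("manifest.json")
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest[stage] = {
        "seed": cfg.seed,
        "version": __version__,
        "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in outputs if p.suffix in (".csv", ".json")},
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    return path


# ---------------------------------------------------------------- stages


def run_simulate(cfg: PipelineConfig) -> list[Path]:
    sim = simulate_cohort(SimConfig(seed=cfg.seed, n_patients=cfg.n_patients, planted_k=cfg.planted_k))
    out_dir = cfg.path("simulated")
    out_dir.mkdir(parents=True, exist_ok=True)
    admins = sim.administrations.copy()
    admins["date"] = pd.to_datetime(admins["date"]).dt.strftime("%Y-%m-%d")
    outputs = [
        _write_csv(admins, out_dir / "administrations.csv"),
        _write_csv(sim.readings, out_dir / "readings.csv"),
    ]
    if sim.truth is not None:
        truth = sim.truth.copy()
        truth["date"] = pd.to_datetime(truth["date"]).dt.strftime("%Y-%m-%d")
        p = out_dir / "truth.json"
        p.write_text(truth.to_json(orient="records"))
        outputs.append(p)
    _write_manifest(cfg, "simulate", [], outputs, {"n_patients": cfg.n_patients, "planted_k": cfg.planted_k})
    log.info("simulate: %d administrations, %d readings", len(admins), len(sim.readings))
    return outputs


def run_domains(cfg: PipelineConfig) -> list[Path]:
    """Build raw record tables and one fuzzy domain per parameter."""
    admins_path = _require(cfg.path("simulated", "administrations.csv"), "simulate")
    readings_path = _require(cfg.path("simulated", "readings.csv"), "simulate")
    admins = pd.read_csv(admins_path)
    readings = pd.read_csv(readings_path)
    schema = [p.name for p in DEFAULT_MONITORING_SCHEMA]

    therapy = build_therapy_records(admins, DEFAULT_DRUG_VOCABULARY, grace=cfg.grace_days)
    monitoring = build_monitoring_records(readings, schema, aggregator=cfg.aggregator)

    # therapy domains: durations in days, upper-tail trim; sparse/constant drug
    # columns inherit the overall-days domain
    overall = domain_from_observations(
        "overall_days",
        therapy["overall_days"].to_numpy(dtype=float),
        mode=cfg.therapy_trim_mode,
        coverage=cfg.trim_coverage,
        overlap_rule=cfg.overlap_rule,
        labels=THERAPY_LABELS,
    )
    therapy_domains = {"overall_days": overall}
    for drug in DEFAULT_DRUG_VOCABULARY:
        vals = therapy[drug].to_numpy(dtype=float)
        vals = vals[vals > 0]
        dom = None
        if vals.size >= cfg.min_obs_for_domain:
            try:
                dom = domain_from_observations(
                    drug, vals, mode=cfg.therapy_trim_mode, coverage=cfg.trim_coverage,
                    overlap_rule=cfg.overlap_rule, labels=THERAPY_LABELS,
                )
            except ValueError:
                dom = None
        if dom is None:
            dom = dataclasses.replace(overall, parameter_id=drug, overlap_rule=overall.overlap_rule + "|shared_overall")
        therapy_domains[drug] = dom

    monitoring_domains = {}
    skipped: list[str] = []
    for name in schema:
        vals = monitoring[name].dropna().to_numpy(dtype=float)
        try:
            if vals.size < cfg.min_obs_for_domain:
                raise ValueError("too few observations")
            monitoring_domains[name] = domain_from_observations(
                name, vals, mode=cfg.monitoring_trim_mode, coverage=cfg.trim_coverage,
                overlap_rule=cfg.overlap_rule, labels=MONITORING_LABELS,
            )
        except ValueError:
            skipped.append(name)

    dom_dir = cfg.path("domains")
    dom_dir.mkdir(parents=True, exist_ok=True)
    ther = therapy.copy()
    ther["date"] = ther["date"].dt.strftime("%Y-%m-%d")
    moni = monitoring.copy()
    moni["date"] = moni["date"].dt.strftime("%Y-%m-%d")
    outputs = [
        _write_csv(ther, cfg.path("domains", "therapy_records.csv")),
        _write_csv(moni, cfg.path("domains", "monitoring_records.csv")),
    ]
    save_domains(therapy_domains, dom_dir / "therapy_domains.json")
    save_domains(monitoring_domains, dom_dir / "monitoring_domains.json")
    (dom_dir / "skipped_parameters.json").write_text(json.dumps(sorted(skipped)))
    outputs += [dom_dir / "therapy_domains.json", dom_dir / "monitoring_domains.json", dom_dir / "skipped_parameters.json"]
    if cfg.charts:
        plot_domain(overall, dom_dir / "fig_domain_overall_days.png")
        outputs.append(dom_dir / "fig_domain_overall_days.png")
    _write_manifest(cfg, "domains", [admins_path, readings_path], outputs,
                    {"coverage": cfg.trim_coverage, "overlap_rule": cfg.overlap_rule, "skipped": sorted(skipped)})
    log.info("domains: %d therapy + %d monitoring domains (%d skipped)",
             len(therapy_domains), len(monitoring_domains), len(skipped))
    return outputs


def run_normalize(cfg: PipelineConfig) -> list[Path]:
    ther_path = _require(cfg.path("domains", "therapy_records.csv"), "domains")
    moni_path = _require(cfg.path("domains", "monitoring_records.csv"), "domains")
    tdom_path = _require(cfg.path("domains", "therapy_domains.json"), "domains")
    mdom_path = _require(cfg.path("domains", "monitoring_domains.json"), "domains")
    therapy = pd.read_csv(ther_path)
    monitoring = pd.read_csv(moni_path)
    therapy_domains = load_domains(tdom_path)
    monitoring_domains = load_domains(mdom_path)
    skipped = json.loads(cfg.path("domains", "skipped_parameters.json").read_text())
    monitoring = monitoring.drop(columns=[c for c in skipped if c in monitoring.columns])

    tnorm = normalize_records(therapy, therapy_domains, zero_is_absent=True)
    mnorm = normalize_records(monitoring, monitoring_domains)
    tuniq = dedup(tnorm)
    muniq = dedup(mnorm)

    pat_dir = cfg.path("patterns")
    pat_dir.mkdir(parents=True, exist_ok=True)
    tnorm_out = tnorm.copy()
    tnorm_out["pattern_id"] = tuniq.record_ids
    mnorm_out = mnorm.copy()
    mnorm_out["pattern_id"] = muniq.record_ids
    outputs = [
        _write_csv(tnorm_out, pat_dir / "therapy_patterns.csv"),
        _write_csv(mnorm_out, pat_dir / "monitoring_patterns.csv"),
        _write_csv(tuniq.to_frame(), pat_dir / "therapy_unique.csv"),
        _write_csv(muniq.to_frame(), pat_dir / "monitoring_unique.csv"),
    ]
    sidecar = {
        "therapy_columns": list(tuniq.columns),
        "monitoring_columns": list(muniq.columns),
        "therapy_domains": str(tdom_path),
        "monitoring_domains": str(mdom_path),
        "skipped_parameters": skipped,
    }
    (pat_dir / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    outputs.append(pat_dir / "sidecar.json")
    _write_manifest(cfg, "normalize", [ther_path, moni_path, tdom_path, mdom_path], outputs, {})
    log.info("normalize: %d therapy records -> %d unique; %d monitoring -> %d unique",
             tuniq.n_records, tuniq.n_unique, muniq.n_records, muniq.n_unique)
    return outputs


def _cluster_one(cfg: PipelineConfig, which: str, k_setting: int | str) -> list[Path]:
    uniq_path = _require(cfg.path("patterns", f"{which}_unique.csv"), "normalize")
    uniq = pd.read_csv(uniq_path)
    X = uniq.drop(columns=["pattern_id", "multiplicity"]).to_numpy(dtype=np.int64)
    model_dir = cfg.path("models")
    model_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    if k_setting == "auto":
        curve = elbow_select(X, k_max=cfg.k_max, seed=cfg.seed, n_init=cfg.n_init, max_iter=cfg.max_iter)
        k = curve.chosen_k
        elbow_csv = _write_csv(curve.to_frame(), model_dir / f"{which}_elbow.csv")
        outputs.append(elbow_csv)
        if cfg.charts:
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots()
            ax.plot(curve.ks, curve.costs, marker="o")
            ax.axvline(k, color="red", ls="--")
            ax.set_xlabel("k")
            ax.set_ylabel("cost")
            fig.savefig(model_dir / f"{which}_elbow.png", dpi=110)
            plt.close(fig)
            outputs.append(model_dir / f"{which}_elbow.png")
    else:
        k = min(int(k_setting), np.unique(X, axis=0).shape[0])
    model = kmodes_fit(X, k, seed=cfg.seed, n_init=cfg.n_init, max_iter=cfg.max_iter)
    model.save(model_dir / f"{which}_model.json")
    outputs.append(model_dir / f"{which}_model.json")
    _write_manifest(cfg, f"cluster_{which}", [uniq_path], outputs,
                    {"k": k, "k_setting": str(k_setting), "n_init": cfg.n_init})
    log.info("cluster %s: k=%d cost=%d", which, model.k, model.cost)
    return outputs


def run_cluster(cfg: PipelineConfig, which: str = "both") -> list[Path]:
    outputs = []
    if which in ("therapy", "both"):
        outputs += _cluster_one(cfg, "therapy", cfg.therapy_k)
    if which in ("monitoring", "both"):
        outputs += _cluster_one(cfg, "monitoring", cfg.monitoring_k)
    return outputs


def run_stays(cfg: PipelineConfig) -> list[Path]:
    tpat_path = _require(cfg.path("patterns", "therapy_patterns.csv"), "normalize")
    mpat_path = _require(cfg.path("patterns", "monitoring_patterns.csv"), "normalize")
    tmod_path = _require(cfg.path("models", "therapy_model.json"), "cluster")
    mmod_path = _require(cfg.path("models", "monitoring_model.json"), "cluster")
    tpat = pd.read_csv(tpat_path)
    mpat = pd.read_csv(mpat_path)
    tmodel = KModesModel.load(tmod_path)
    mmodel = KModesModel.load(mmod_path)

    tlab = tpat[["patient_id", "date"]].copy()
    tlab["cluster"] = tmodel.labels[tpat["pattern_id"].to_numpy()]
    mlab = mpat[["patient_id", "date", "hour"]].copy()
    mlab["cluster"] = mmodel.labels[mpat["pattern_id"].to_numpy()]
    stay = build_stay_table(tlab, mlab)

    stays_dir = cfg.path("stays")
    stays_dir.mkdir(parents=True, exist_ok=True)
    stay_out = stay.copy()
    stay_out["date"] = stay_out["date"].dt.strftime("%Y-%m-%d")
    outputs = [_write_csv(stay_out, stays_dir / "stay_table.csv")]

    # Table 1/2-shaped: per-cluster fuzzy subset frequencies over unique patterns
    tuniq = pd.read_csv(cfg.path("patterns", "therapy_unique.csv"))
    muniq = pd.read_csv(cfg.path("patterns", "monitoring_unique.csv"))
    tfreq = subset_frequencies(tmodel.labels, tuniq.drop(columns=["pattern_id", "multiplicity"]).to_numpy())
    mfreq = subset_frequencies(mmodel.labels, muniq.drop(columns=["pattern_id", "multiplicity"]).to_numpy())
    outputs.append(_write_csv(tfreq, stays_dir / "therapy_cluster_frequencies.csv", index=True))
    outputs.append(_write_csv(mfreq, stays_dir / "monitoring_cluster_frequencies.csv", index=True))

    cont = contingency(stay)
    outputs.append(_write_csv(cont.counts, stays_dir / "contingency_counts.csv", index=True))
    outputs.append(_write_csv(cont.freq.round(6), stays_dir / "contingency_freq.csv", index=True))

    tests: dict[str, object] = {}
    try:
        stat, dof, p = chi_square(cont.counts.to_numpy())
        tests["therapy_vs_monitoring"] = {"chi2": stat, "dof": dof, "p": p}
    except ValueError as exc:
        tests["therapy_vs_monitoring"] = {"error": str(exc)}
    (stays_dir / "chisquare.json").write_text(json.dumps(tests, indent=1))
    outputs.append(stays_dir / "chisquare.json")

    overall_codes = tpat[["patient_id", "date", "overall_days"]].rename(columns={"overall_days": "code"})
    summary = nabtcl_summary(stay, overall_codes)
    outputs.append(_write_csv(summary.stay_counts.rename("n_stays").to_frame(), stays_dir / "nabtcl_stay_counts.csv", index=True))
    outputs.append(_write_csv(summary.hour_counts.rename("n_hours").to_frame(), stays_dir / "nabtcl_hour_counts.csv", index=True))
    outputs.append(_write_csv(summary.therapy_mix.round(6), stays_dir / "nabtcl_therapy_mix.csv", index=True))
    outputs.append(_write_csv(summary.monitoring_mix.round(6), stays_dir / "nabtcl_monitoring_mix.csv", index=True))
    if summary.duration_mix is not None:
        outputs.append(_write_csv(summary.duration_mix.round(6), stays_dir / "nabtcl_duration_mix.csv", index=True))

    _write_manifest(cfg, "stays", [tpat_path, mpat_path, tmod_path, mmod_path], outputs, {})
    log.info("stays: %d treated patient-days, %d monitored hours", len(stay), cont.grand_total)
    return outputs


def run_report(cfg: PipelineConfig) -> list[Path]:
    stay_path = _require(cfg.path("stays", "stay_table.csv"), "stays")
    tdom_path = _require(cfg.path("domains", "therapy_domains.json"), "domains")
    mpat_path = _require(cfg.path("patterns", "monitoring_patterns.csv"), "normalize")
    stay = pd.read_csv(stay_path)
    report_dir = cfg.path("report")
    report_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    overall = load_domains(tdom_path)["overall_days"]
    plot_domain(overall, report_dir / "fig_domain.png")
    outputs.append(report_dir / "fig_domain.png")

    # pick the first patient with >= 14 monitored hours for the figure analogs
    monitored = (stay[list(HOUR_COLUMNS)] > 0).sum(axis=1)
    per_patient = monitored.groupby(stay["patient_id"]).sum()
    candidates = per_patient[per_patient >= 14]
    pid = (candidates if len(candidates) else per_patient).idxmax() if len(per_patient) else None
    if pid is not None:
        window = extract_stay_window(stay, pid, n_hours=14)
        if len(window):
            stay_chart(window, report_dir / "fig_stay_clusters.png")
            outputs.append(report_dir / "fig_stay_clusters.png")
        mpat = pd.read_csv(mpat_path)
        sub = mpat[mpat["patient_id"] == pid].sort_values(["date", "hour"]).head(14)
        value_cols = [c for c in sub.columns if c not in ("patient_id", "date", "hour", "pattern_id")]
        # most informative parameters first: highest non-null share in the window
        nonnull = (sub[value_cols] > 0).sum().sort_values(ascending=False)
        ribbon_cols = list(nonnull.index[:12])
        plot_fuzzified_ribbon(sub[ribbon_cols].reset_index(drop=True), report_dir / "fig_monitoring_ribbon.png")
        outputs.append(report_dir / "fig_monitoring_ribbon.png")

    _write_manifest(cfg, "report", [stay_path, tdom_path], outputs, {"patient": str(pid)})
    log.info("report: figures for patient %s", pid)
    return outputs


STAGES = ("simulate", "domains", "normalize", "cluster", "stays", "report")


def run_stage(stage: str, cfg: PipelineConfig) -> list[Path]:
    if stage == "all":
        return run_all(cfg)
    runners = {
        "simulate": run_simulate,
        "domains": run_domains,
        "normalize": run_normalize,
        "cluster": run_cluster,
        "stays": run_stays,
        "report": run_report,
    }
    if stage not in runners:
        raise ValueError(f"unknown stage {stage!r} (expected one of {STAGES + ('all',)})")
    return runners[stage](cfg)


def run_all(cfg: PipelineConfig) -> list[Path]:
    outputs: list[Path] = []
    for stage in STAGES:
        outputs += run_stage(stage, cfg)
    return outputs
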