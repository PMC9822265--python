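"""Config-driven orchestration: simulate -> extract -> quantify -> test.

A run is a pure function of (RunConfig, seed).  It generates a synthetic
cohort and anatomy with ground truth, extracts evoked/train/intrinsic
feature tables, computes puncta-density and intensity profiles, runs the
statistical analysis plan (layer/position Friedman with Kendall's W and
pairwise Wilcoxon post-hocs, Kruskal-Wallis with Dunn post-hocs across cell
classes, Mann-Whitney on E-I ratios, Kolmogorov-Smirnov on train E-I
distributions, paired Wilcoxon on first vs last train pulse, and
position regressions), and writes every table as tab-delimited text plus a
JSON log with the seed and config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import anatomy, intrinsic, stats, synaptic, synth
from .recordings import Cohort, Layer, ProtocolKind, write_cohort

__all__ = ["RunConfig", "RunReport", "run_experiment", "load_config",
           "extract_evoked_table", "extract_train_table",
           "extract_intrinsic_table", "classification_table"]


@dataclass
class RunConfig:
    """Serializable description of one synthetic experiment."""

    cohort_scale: float = 0.2
    noise_sd_mV: float = 0.2
    train_frequencies_hz: Tuple[float, ...] = (10.0,)
    include_intrinsic: bool = False
    n_slices: int = 8
    puncta_rates_mm3: Dict[str, float] = field(
        default_factory=lambda: {
            "L1": 4790.0, "L2": 1200.0, "L3": 300.0, "L5a": 400.0, "L5b": 800.0
        }
    )
    ml_gradient: Tuple[float, ...] = (1.5, 1.25, 1.1, 1.0, 0.85, 0.7)
    profile_peak_um: float = 60.0
    profile_width_um: float = 45.0
    profile_baseline: float = 35.0
    profile_amplitude: float = 120.0
    profile_noise_sd: float = 6.0
    profile_n_points: int = 120

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("train_frequencies_hz", "ml_gradient"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> Dict:
        out = dataclasses.asdict(self)
        out["train_frequencies_hz"] = list(self.train_frequencies_hz)
        out["ml_gradient"] = list(self.ml_gradient)
        return out

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    return RunConfig.from_dict(raw)


@dataclass
class RunReport:
    cells: pd.DataFrame
    evoked: pd.DataFrame
    train: pd.DataFrame
    intrinsic: pd.DataFrame
    layer_density: pd.DataFrame
    ml_density: pd.DataFrame
    intensity_profile: pd.DataFrame
    stats: pd.DataFrame
    recovery: pd.DataFrame
    log: Dict


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def extract_evoked_table(
    cohort: Cohort, condition: str = "baseline"
) -> pd.DataFrame:
    """One row per cell: single-pulse evoked-response features."""
    rows = []
    for cell in cohort.cells:
        sweeps = cohort.cell_sweeps(
            cell.cell_id, ProtocolKind.OPTO_PULSE, condition
        )
        if not sweeps:
            continue
        r = synaptic.measure_evoked(sweeps)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "cell_class": cell.cell_class.value,
                "layer": cell.layer.value,
                "condition": condition,
                "ml_distance_um": cell.ml_distance_um,
                "dv_depth_mm": cell.dv_depth_mm,
                "baseline_vm_mV": r.baseline_vm_mV,
                "epsp_amp_mV": r.epsp_amp_mV,
                "ipsp_amp_mV": r.ipsp_amp_mV,
                "classification": r.classification,
                "ei_ratio": np.nan if r.ei_ratio is None else r.ei_ratio,
                "latency_ms": np.nan if r.latency_ms is None else r.latency_ms,
                "half_width_ms": np.nan if r.half_width_ms is None else r.half_width_ms,
                "n_sweeps_averaged": r.n_sweeps_averaged,
            }
        )
    return pd.DataFrame(rows)


def extract_train_table(
    cohort: Cohort, condition: str = "baseline"
) -> pd.DataFrame:
    """Long-format table: one row per cell x frequency x pulse."""
    rows = []
    for cell in cohort.cells:
        sweeps = cohort.cell_sweeps(
            cell.cell_id, ProtocolKind.OPTO_TRAIN, condition
        )
        by_freq: Dict[float, List] = {}
        for s in sweeps:
            by_freq.setdefault(s.protocol.param("frequency_hz"), []).append(s)
        for freq, group in sorted(by_freq.items()):
            tr = synaptic.measure_train(group)
            for k in range(tr.n_pulses):
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "cell_class": cell.cell_class.value,
                        "frequency_hz": freq,
                        "pulse": k + 1,
                        "epsp_amp_mV": tr.epsp_amp_mV[k],
                        "ipsp_amp_mV": tr.ipsp_amp_mV[k],
                        "ei_ratio": tr.ei_ratio[k],
                    }
                )
    return pd.DataFrame(rows)


def extract_intrinsic_table(
    cohort: Cohort, condition: str = "baseline"
) -> pd.DataFrame:
    rows = []
    for cell in cohort.cells:
        step = cohort.cell_sweeps(cell.cell_id, ProtocolKind.CURRENT_STEP, condition)
        ramp = cohort.cell_sweeps(cell.cell_id, ProtocolKind.CURRENT_RAMP, condition)
        zap = cohort.cell_sweeps(cell.cell_id, ProtocolKind.ZAP, condition)
        if not (step or ramp or zap):
            continue
        profile = intrinsic.extract_intrinsic_profile(
            step_sweep=step[0] if step else None,
            ramp_sweep=ramp[0] if ramp else None,
            zap_sweep=zap[0] if zap else None,
        )
        row = {"cell_id": cell.cell_id, "cell_class": cell.cell_class.value}
        row.update(
            {
                "resting_vm_mV": profile.resting_vm_mV,
                "input_resistance_MOhm": profile.input_resistance_MOhm,
                "tau_m_ms": profile.tau_m_ms,
                "sag_ratio": profile.sag_ratio,
                "rheobase_pA": profile.rheobase_pA,
                "ap_threshold_mV": profile.ap_threshold_mV,
                "ap_amplitude_mV": profile.ap_amplitude_mV,
                "ap_duration_ms": profile.ap_duration_ms,
                "resonance_freq_hz": profile.resonance_freq_hz,
                "resonant": profile.resonant,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def classification_table(classifications: Sequence[str]) -> pd.DataFrame:
    """Tabulate response classifications into counts and percentages."""
    counts: Dict[str, int] = {}
    for c in classifications:
        counts[c] = counts.get(c, 0) + 1
    total = len(classifications)
    rows = [
        {"classification": c, "n": n, "percent": 100.0 * n / total}
        for c, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistics plan
# ---------------------------------------------------------------------------


def _stat_row(analysis: str, res: stats.TestResult) -> Dict:
    return {
        "analysis": analysis,
        "test": res.test,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "effect_size": res.effect_size,
        "effect_size_name": res.effect_size_name,
        "method": res.method,
    }


def _run_stats_plan(
    evoked: pd.DataFrame,
    train: pd.DataFrame,
    layer_density: pd.DataFrame,
    ml_density: pd.DataFrame,
) -> pd.DataFrame:
    rows: List[Dict] = []

    # puncta density across layers and mediolateral position (repeated
    # measures over slices), with pairwise Wilcoxon post-hocs
    if not layer_density.empty:
        wide = layer_density.pivot(index="slice", columns="layer",
                                   values="density_mm3")
        wide = wide[[l.value for l in Layer]]
        res = stats.friedman(wide.to_numpy())
        rows.append(_stat_row("puncta_density_by_layer", res))
        others = [l.value for l in Layer if l is not Layer.L1]
        pvals = []
        for other in others:
            w = stats.wilcoxon_signed_rank(
                wide["L1"].to_numpy(), wide[other].to_numpy()
            )
            pvals.append(w.p_value)
            rows.append(
                _stat_row(f"puncta_density_L1_vs_{other}", w)
            )
        adj = stats.bonferroni(pvals, m=len(pvals))
        for other, p_adj in zip(others, adj):
            rows.append(
                {
                    "analysis": f"puncta_density_L1_vs_{other}_bonferroni",
                    "test": "bonferroni",
                    "statistic": np.nan,
                    "df": np.nan,
                    "p_value": p_adj,
                    "effect_size": np.nan,
                    "effect_size_name": None,
                    "method": "adjustment",
                }
            )
    if not ml_density.empty:
        wide = ml_density.pivot(index="slice", columns="bin_start_um",
                                values="density_mm3")
        res = stats.friedman(wide.to_numpy())
        rows.append(_stat_row("puncta_density_by_ml_position", res))

    principal = evoked[
        evoked["cell_class"].isin(["L2_SC", "L2_PC", "L3_PC", "L5a_PC", "L5b_PC"])
    ]
    sub = principal[principal["classification"].isin(
        ["excitatory", "biphasic", "inhibitory"])]

    # EPSP amplitude across principal cell classes (Kruskal-Wallis + Dunn)
    groups = []
    labels = []
    for cls, g in sub.groupby("cell_class"):
        amps = g.loc[g["epsp_amp_mV"] > 0, "epsp_amp_mV"].to_numpy()
        if len(amps) >= 2:
            groups.append(amps)
            labels.append(cls)
    if len(groups) >= 2:
        res = stats.kruskal_wallis(groups)
        if len(groups) >= 3:
            res.posthoc = stats.dunn_posthoc(groups, labels)
        rows.append(_stat_row("epsp_amp_by_cell_class", res))

    # E-I ratio: stellate vs pyramidal (Mann-Whitney)
    sc_ei = sub.loc[sub["cell_class"] == "L2_SC", "ei_ratio"].dropna().to_numpy()
    pc_ei = sub.loc[sub["cell_class"] == "L2_PC", "ei_ratio"].dropna().to_numpy()
    if len(sc_ei) >= 2 and len(pc_ei) >= 2:
        rows.append(_stat_row("ei_ratio_sc_vs_pc", stats.mann_whitney_u(pc_ei, sc_ei)))

    # E-I ratio vs anatomical position (simple linear regressions)
    for cls in ("L2_SC", "L2_PC"):
        g = sub[(sub["cell_class"] == cls)].dropna(subset=["ei_ratio"])
        for axis, col in (("ml", "ml_distance_um"), ("dv", "dv_depth_mm")):
            if len(g) >= 3 and g[col].nunique() > 1:
                reg = stats.linear_regression_f(g[col], g["ei_ratio"])
                rows.append(
                    {
                        "analysis": f"ei_ratio_vs_{axis}_{cls}",
                        "test": "linear_regression_f",
                        "statistic": reg.f_statistic,
                        "df": f"{reg.df[0]},{reg.df[1]}",
                        "p_value": reg.p_value,
                        "effect_size": reg.r_squared,
                        "effect_size_name": "r_squared",
                        "method": "exact",
                    }
                )

    # train dynamics: pulse 1 vs pulse 10 (paired Wilcoxon), and
    # distribution comparison of E-I ratios (KS)
    if not train.empty:
        for freq, tf in train.groupby("frequency_hz"):
            last_pulse = int(tf["pulse"].max())
            for cls in ("L2_SC", "L2_PC"):
                g = tf[tf["cell_class"] == cls]
                p1 = g[g["pulse"] == 1].set_index("cell_id")
                pN = g[g["pulse"] == last_pulse].set_index("cell_id")
                shared = p1.index.intersection(pN.index)
                for feature in ("ipsp_amp_mV", "epsp_amp_mV", "ei_ratio"):
                    a = p1.loc[shared, feature].to_numpy(dtype=float)
                    b = pN.loc[shared, feature].to_numpy(dtype=float)
                    ok = np.isfinite(a) & np.isfinite(b)
                    if ok.sum() >= 2 and np.any(a[ok] != b[ok]):
                        res = stats.wilcoxon_signed_rank(b[ok], a[ok])
                        rows.append(
                            _stat_row(
                                f"train{int(freq)}_{cls}_{feature}_pulse1_vs_{last_pulse}",
                                res,
                            )
                        )
            sc = tf[(tf["cell_class"] == "L2_SC") & (tf["pulse"] == last_pulse)]
            pc = tf[(tf["cell_class"] == "L2_PC") & (tf["pulse"] == last_pulse)]
            sc_v = sc["ei_ratio"].dropna().to_numpy()
            pc_v = pc["ei_ratio"].dropna().to_numpy()
            if len(sc_v) >= 2 and len(pc_v) >= 2:
                rows.append(
                    _stat_row(
                        f"train{int(freq)}_ei_ratio_sc_vs_pc_pulse{last_pulse}",
                        stats.ks_two_sample(sc_v, pc_v),
                    )
                )
    return pd.DataFrame(rows)


def _recovery_summary(
    evoked: pd.DataFrame, truth: synth.CohortGroundTruth
) -> pd.DataFrame:
    """Extracted-vs-ground-truth bias and RMSE for the key parameters."""
    rows = []
    pairs = {"epsp_amp_mV": [], "ipsp_amp_mV": [], "ei_ratio": []}
    n_class_match = 0
    n_class = 0
    for _, row in evoked.iterrows():
        gt = truth.cells.get(row["cell_id"])
        if gt is None:
            continue
        n_class += 1
        n_class_match += row["classification"] == gt.response_class
        if gt.response_class in ("excitatory", "inhibitory", "biphasic"):
            pairs["epsp_amp_mV"].append((row["epsp_amp_mV"], gt.epsp_amp_mV))
            pairs["ipsp_amp_mV"].append((row["ipsp_amp_mV"], gt.ipsp_amp_mV))
            if gt.ei_ratio is not None and np.isfinite(row["ei_ratio"]):
                pairs["ei_ratio"].append((row["ei_ratio"], gt.ei_ratio))
    for name, vals in pairs.items():
        if not vals:
            continue
        est = np.array([v[0] for v in vals])
        true = np.array([v[1] for v in vals])
        rows.append(
            {
                "parameter": name,
                "n": len(vals),
                "bias": float(np.mean(est - true)),
                "rmse": float(np.sqrt(np.mean((est - true) ** 2))),
            }
        )
    if n_class:
        rows.append(
            {
                "parameter": "classification_accuracy",
                "n": n_class,
                "bias": np.nan,
                "rmse": float(n_class_match / n_class),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Top-level run
# ---------------------------------------------------------------------------


def run_experiment(
    config: RunConfig,
    seed: int,
    out_dir: Optional[Path | str] = None,
    write_sweeps: bool = False,
) -> RunReport:
    """Execute the full simulate -> extract -> quantify -> test pipeline."""
    t_start = time.time()
    cohort_cfg = synth.default_cohort_config(
        scale=config.cohort_scale,
        noise_sd_mV=config.noise_sd_mV,
        include_intrinsic=config.include_intrinsic,
        train_frequencies_hz=config.train_frequencies_hz,
    )
    cohort, truth = synth.generate_cohort(cohort_cfg, seed=seed)
    evoked = extract_evoked_table(cohort)
    train = extract_train_table(cohort)
    intr = extract_intrinsic_table(cohort) if config.include_intrinsic else pd.DataFrame()

    # anatomy: n_slices independent puncta fields + one intensity profile
    geometry = synth.default_layer_geometry()
    rates = {Layer(k): v for k, v in config.puncta_rates_mm3.items()}
    layer_rows = []
    ml_rows = []
    anat_seeds = np.random.SeedSequence([seed, 999]).spawn(config.n_slices + 1)
    for s_idx in range(config.n_slices):
        puncta, _ = synth.generate_puncta(
            geometry, rates, ml_gradient=config.ml_gradient,
            seed=anat_seeds[s_idx],
        )
        ld = anatomy.layer_density_profile(puncta, geometry)
        ld["slice"] = s_idx
        layer_rows.append(ld)
        ml = anatomy.mediolateral_profile(puncta, geometry)
        ml["slice"] = s_idx
        ml_rows.append(ml)
    layer_density = pd.concat(layer_rows, ignore_index=True)
    ml_density = pd.concat(ml_rows, ignore_index=True)
    profile, _ = synth.generate_intensity_profile(
        peak_pos_um=config.profile_peak_um,
        width_um=config.profile_width_um,
        baseline=config.profile_baseline,
        amplitude=config.profile_amplitude,
        noise_sd=config.profile_noise_sd,
        n_points=config.profile_n_points,
        seed=anat_seeds[-1],
    )
    profile["normalized"] = anatomy.normalize_profile(profile["intensity"])

    stats_table = _run_stats_plan(evoked, train, layer_density, ml_density)
    recovery = _recovery_summary(evoked, truth)

    cells = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "cell_class": c.cell_class.value,
                "layer": c.layer.value,
                "ml_distance_um": c.ml_distance_um,
                "dv_depth_mm": c.dv_depth_mm,
                "resting_vm_mV": c.resting_vm_mV,
                "series_resistance_MOhm": c.series_resistance_MOhm,
                "included": c.included,
                "true_response_class": truth.cells[c.cell_id].response_class,
            }
            for c in cohort.cells
        ]
    )

    log = {
        "seed": seed,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "n_cells": len(cohort.cells),
        "elapsed_s": round(time.time() - t_start, 2),
    }
    report = RunReport(
        cells=cells,
        evoked=evoked,
        train=train,
        intrinsic=intr,
        layer_density=layer_density,
        ml_density=ml_density,
        intensity_profile=profile,
        stats=stats_table,
        recovery=recovery,
        log=log,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("cells", "evoked", "train", "intrinsic", "layer_density",
                     "ml_density", "intensity_profile", "stats", "recovery"):
            table = getattr(report, name)
            if isinstance(table, pd.DataFrame) and not table.empty:
                table.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                             float_format="%.10g")
        (out / "log.json").write_text(json.dumps(log, indent=2) + "\n")
        if write_sweeps:
            write_cohort(cohort, out / "manifest.tsv", out / "sweeps")
    return report
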