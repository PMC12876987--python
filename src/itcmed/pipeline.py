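"""End-to-end orchestration: simulate -> fit-itc -> stats -> mediate -> report.

Each stage reads and writes standard formats (CSV, JSON, YAML, NIfTI-1) so a
run can be resumed or audited from its serialized outputs.  All randomness
flows from one top-level seed through named ``numpy.random.SeedSequence``
substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (ClinicalScoreSpec, CohortSpec, sample_clinical,
                     sample_truth, simulate_choice_table)
from .design import DesignConfig, build_design_grid
from .estimation import estimate_participants, remove_extreme_outliers
from .mediation import (SIGNS_DISCOUNT_RATE, SIGNS_SENSITIVITY,
                        MediationConfig, run_whole_brain)
from .stats import group_comparison_battery, symptom_correlation_battery
from .volumes import (VolumeSpec, Region, load_cohort_niftis,
                      save_cohort_niftis, save_truth, simulate_gmd_volumes)

CHOICE_COLUMNS = ("participant_id", "group", "reward_type", "ss_amount",
                  "ss_delay", "ll_amount", "ll_delay", "chose_ll")


@dataclass
class RunConfig:
    """Configured pipeline run; every output manifest records the seed."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    # simulation
    cohort: CohortSpec = field(default_factory=CohortSpec)
    volume: VolumeSpec = field(default_factory=VolumeSpec)
    outcome_noise_sd: float = 0.3
    write_volumes: bool = True
    # estimation
    inconsistency_alpha: float = 0.05
    interpolation_scale: str = "log"
    outlier_policy: str = "pooled"  # or "none"
    # stats
    bonferroni_m: int = 8
    drop_interpolated: bool = False
    # mediation
    n_boot: int = 10_000
    q: float = 0.05
    pooling: str = "across_paths"
    min_cluster_size: int = 5
    mediation_reward: str = "money"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        if "log_k" in cohort_raw:
            cohort_raw["log_k"] = {
                (tuple(k.split("/")) if isinstance(k, str) else tuple(k)): tuple(v)
                for k, v in cohort_raw["log_k"].items()}
        if "clinical" in cohort_raw:
            cohort_raw["clinical"] = {k: ClinicalScoreSpec(**v) for k, v
                                      in cohort_raw["clinical"].items()}
        cohort = CohortSpec(**cohort_raw)
        vol_raw = raw.pop("volume", {})
        if "regions" in vol_raw:
            vol_raw["regions"] = tuple(
                Region(**{**r, "corner": tuple(r["corner"]),
                          "size": tuple(r["size"])})
                for r in vol_raw["regions"])
        if "shape" in vol_raw:
            vol_raw["shape"] = tuple(vol_raw["shape"])
        volume = VolumeSpec(**vol_raw)
        return cls(cohort=cohort, volume=volume, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"]["log_k"] = {f"{g}/{r}": list(v) for (g, r), v
                                in self.cohort.log_k.items()}
        d["cohort"]["clinical"] = {k: dataclasses.asdict(v) for k, v
                                   in self.cohort.clinical.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class ValidationReport:
    fatal: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(choices: pd.DataFrame, clinical: pd.DataFrame | None = None,
                    volumes: np.ndarray | None = None,
                    mask: np.ndarray | None = None,
                    n_trials_expected: int = 32) -> ValidationReport:
    """Check schema, trial counts, binary choices and volume congruence."""
    fatal, warn = [], []
    missing = [c for c in CHOICE_COLUMNS if c not in choices.columns]
    if missing:
        fatal.append(f"choice table missing columns: {missing}")
        return ValidationReport(fatal, warn)
    bad = set(pd.unique(choices["chose_ll"])) - {0, 1}
    if bad:
        fatal.append(f"non-binary choice codes: {sorted(bad)}")
    if (choices["ll_amount"] <= choices["ss_amount"]).any():
        fatal.append("trials with LL amount <= SS amount")
    for (pid, reward), sub in choices.groupby(["participant_id", "reward_type"]):
        if len(sub) != n_trials_expected:
            warn.append(f"participant {pid} has {len(sub)} {reward} trials "
                        f"(expected {n_trials_expected})")
    if clinical is not None:
        ids = set(choices["participant_id"]) - set(clinical["participant_id"])
        if ids:
            warn.append(f"{len(ids)} participants missing from the clinical table")
    if volumes is not None and mask is not None:
        if volumes.shape[1:] != mask.shape:
            fatal.append(f"volume grid {volumes.shape[1:]} does not match mask "
                         f"grid {mask.shape}")
    return ValidationReport(fatal, warn)


def simulate_study(cohort_spec: CohortSpec, volume_spec: VolumeSpec,
                   outcome_noise_sd: float = 0.3, seed: int | None = 0,
                   design_config: DesignConfig | None = None) -> dict:
    """Full synthetic study with behaviour coupled to brain structure.

    The GMD volumes' outcome (direct group effect + planted regional
    coupling + noise) is mapped monotonically (per-group standardization)
    onto the cohort's true money log(k) scale, so atrophy regions with
    planted coupling genuinely mediate the group difference in the
    *behavioural* discount rate that the estimation stage recovers from
    choices.  Food log(k) and clinical scores follow the cohort spec's
    copula around that latent.
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rng_truth, rng_vol, rng_food, rng_clin, rng_choice = (
        np.random.default_rng(s) for s in ss.spawn(5))
    design = build_design_grid(design_config or DesignConfig())
    truth = sample_truth(cohort_spec, rng_truth)
    vols, outcome, maps = simulate_gmd_volumes(
        volume_spec, truth, outcome_noise_sd=outcome_noise_sd, rng=rng_vol)

    # map the structural outcome onto the cohort's money log-k marginals
    z_money = np.empty(len(truth))
    log_k_money = np.empty(len(truth))
    for g in ("bvftd", "control"):
        sel = (truth["group"] == g).to_numpy()
        mu, sd = cohort_spec.log_k[(g, "money")]
        z = (outcome[sel] - outcome[sel].mean()) / outcome[sel].std()
        z_money[sel] = z
        log_k_money[sel] = mu + sd * z
    rho = cohort_spec.money_food_rho
    z_food = rho * z_money + np.sqrt(1 - rho ** 2) * \
        rng_food.standard_normal(len(truth))
    log_k_food = np.empty(len(truth))
    for g in ("bvftd", "control"):
        sel = (truth["group"] == g).to_numpy()
        mu, sd = cohort_spec.log_k[(g, "food")]
        log_k_food[sel] = mu + sd * z_food[sel]
    truth = truth.assign(log_k_money=log_k_money, log_k_food=log_k_food,
                         z_money=z_money, z_food=z_food)

    clinical = sample_clinical(cohort_spec, truth, rng_clin)
    choices = simulate_choice_table(truth, design, rng_choice)
    return {"design": design, "truth": truth, "clinical": clinical,
            "choices": choices, "volumes": vols, "mask": maps["mask"],
            "truth_maps": maps, "structural_outcome": outcome}


class StageError(RuntimeError):
    """A pipeline stage failed; the manifest marks partial outputs."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest.

    Outputs under ``config.out_dir``: choices.csv, clinical.csv, truth
    tables, estimates.csv, stats CSVs, mediation maps per outcome, and
    manifest.json.  Reruns with the same config and seed are byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "errors": [], "stages": {}}

    # --- simulate -----------------------------------------------------
    sim = simulate_study(config.cohort, config.volume,
                         outcome_noise_sd=config.outcome_noise_sd,
                         seed=config.seed)
    sim["choices"].to_csv(out / "choices.csv", index=False)
    sim["clinical"].to_csv(out / "clinical.csv", index=False)
    save_truth(out, sim["truth"], sim["truth_maps"], config.volume)
    if config.write_volumes:
        save_cohort_niftis(out / "volumes", sim["volumes"], sim["truth"],
                           config.volume)
    manifest["stages"]["simulate"] = {
        "n_bvftd": int((sim["truth"]["group"] == "bvftd").sum()),
        "n_control": int((sim["truth"]["group"] == "control").sum()),
    }

    report = validate_inputs(sim["choices"], sim["clinical"],
                             sim["volumes"], sim["mask"])
    if not report.ok:
        manifest["errors"] = report.fatal
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(f"validation failed: {report.fatal}")

    # --- fit-itc ------------------------------------------------------
    estimates = estimate_participants(sim["choices"],
                                      inconsistency_alpha=config.inconsistency_alpha,
                                      interpolation_scale=config.interpolation_scale)
    if config.outlier_policy == "pooled":
        for col in ("log_k", "beta_amount"):
            for reward, sub in estimates.groupby("reward_type"):
                _, removed = remove_extreme_outliers(sub[col].to_numpy())
                idx = sub.index[removed]
                estimates.loc[idx, col] = np.nan
                manifest["stages"].setdefault("outliers", []).extend(
                    [{"participant_id": estimates.loc[i, "participant_id"],
                      "reward_type": reward, "variable": col} for i in idx])
    estimates.to_csv(out / "estimates.csv", index=False)
    imput = estimates[estimates["method"] != "logistic_fit"]
    manifest["stages"]["fit_itc"] = {
        "n_estimates": int(len(estimates)),
        "imputed": imput.groupby(["group", "reward_type", "method"],
                                 dropna=False).size()
                        .reset_index(name="n").to_dict("records"),
    }

    # --- stats --------------------------------------------------------
    groups = group_comparison_battery(estimates, sim["clinical"],
                                      drop_interpolated=config.drop_interpolated)
    symptoms = symptom_correlation_battery(estimates, sim["clinical"],
                                           m=config.bonferroni_m)
    groups.to_csv(out / "group_tests.csv", index=False)
    symptoms.to_csv(out / "symptom_correlations.csv", index=False)
    manifest["stages"]["stats"] = {"n_group_tests": int(len(groups)),
                                   "n_correlations": int(len(symptoms))}

    # --- mediate ------------------------------------------------------
    med_cfg = MediationConfig(n_boot=config.n_boot, q=config.q,
                              seed=config.seed, pooling=config.pooling,
                              min_cluster_size=config.min_cluster_size)
    ids = sim["truth"]["participant_id"]
    X = (sim["truth"]["group"] == "bvftd").to_numpy(float)
    med_summary = {}
    for outcome_col, signs in (("log_k", SIGNS_DISCOUNT_RATE),
                               ("beta_amount", SIGNS_SENSITIVITY)):
        sub = estimates[estimates["reward_type"] == config.mediation_reward]
        y = sub.set_index("participant_id")[outcome_col].reindex(ids).to_numpy()
        maps = run_whole_brain(sim["volumes"], sim["mask"], X, y,
                               config=med_cfg, sign_constraints=signs)
        maps.save(out / f"mediation_{outcome_col}", config.volume.affine())
        med_summary[outcome_col] = {
            "fdr_cutoff": maps.fdr_cutoff,
            "n_conjunction_voxels": int(maps.conjunction_masks["primary"].sum()),
            "n_clusters": int(len(maps.clusters)),
        }
    manifest["stages"]["mediate"] = med_summary

    # --- report -------------------------------------------------------
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    lines = ["pipeline run report", f"seed: {config.seed}", ""]
    for _, row in groups.iterrows():
        lines.append(f"{row['outcome']}/{row['reward_type']}: W={row['W']:.1f} "
                     f"p={row['p']:.4f} r={row['effect_size_r']:.2f}")
    for outcome_col, s in med_summary.items():
        lines.append(f"mediation {outcome_col}: cutoff={s['fdr_cutoff']:.4g} "
                     f"conjunction voxels={s['n_conjunction_voxels']} "
                     f"clusters={s['n_clusters']}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return manifest
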