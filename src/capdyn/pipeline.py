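"""End-to-end orchestration: synth -> cluster -> dynamics -> null ->
energy -> infer, with one config, one seed ledger, and a JSON manifest.

Each stage derives its own named seed from the run seed, writes its
outputs as plain-text files under the run directory, and records their
SHA-256 digests in the manifest; re-running with an unchanged config
reuses any stage whose recorded input digests still match (content-
addressed caching), and two runs from the same config and seed produce
identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clustering as cl
from . import control as ct
from . import dynamics as dy
from . import inference as inf
from . import io as capio
from . import nulls
from . import synthetic as syn
from .datatypes import ValidationError

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict[str, int] = field(default_factory=dict)
    stage_inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    cached: list[str] = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "capdyn_run",
    "synth": {},  # SyntheticConfig overrides; set to None to load from disk
    "data": None,  # {"bold_dir":..., "tr":..., "parcellation":..., "clinical":..., "connectome_dir":...}
    "cluster": {"k_min": 2, "k_max": 8, "n_restarts": 10, "select": True, "k": 4},
    "dynamics": {"normalization": "joint"},
    "null": {"enabled": False, "n_surrogates": 10, "mode": "independent"},
    "energy": {"enabled": True, "rho": 1.0, "horizon": 1.0,
               "n_time_steps": 1001, "norm_c": 1.0, "state_scale": "raw"},
    "infer": {"scores": ["QIDS", "MASQ_AD"], "adjust": "bh"},
}


def _merge(defaults: dict, overrides: dict | None) -> dict:
    out = {}
    for key, val in defaults.items():
        if overrides and key in overrides:
            if isinstance(val, dict) and isinstance(overrides[key], dict):
                out[key] = {**val, **overrides[key]}
            else:
                out[key] = overrides[key]
        else:
            out[key] = val
    if overrides:
        for key in overrides:
            if key not in out:
                out[key] = overrides[key]
    return out


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % 2**31


def run_pipeline(config: dict | None = None) -> RunManifest:
    """Execute the requested stages in dependency order.

    The energy arm runs only when connectomes are available (mirroring a
    cohort where only a subsample has diffusion imaging); a missing
    optional arm is skipped with an explicit notice. Any stage failure
    aborts with the stage name and seed in the raised error.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    prev_path = out_dir / "manifest.json"
    prev = json.loads(prev_path.read_text()) if prev_path.exists() else {}

    def record(stage: str, paths: dict[str, Path]) -> None:
        for name, p in paths.items():
            manifest.outputs[f"{stage}/{name}"] = _digest(p)

    def cache_hit(stage: str, input_key: str, expected: list[str]) -> bool:
        if prev.get("stage_inputs", {}).get(stage) != input_key:
            return False
        for name in expected:
            rec = prev.get("outputs", {}).get(f"{stage}/{name}")
            p = out_dir / name
            if rec is None or not p.exists() or _digest(p) != rec:
                return False
        return True

    # ---- stage: synth / load -------------------------------------------
    stage = "synth"
    seed = _stage_seed(cfg["seed"], stage)
    manifest.stage_seeds[stage] = seed
    try:
        if cfg["synth"] is not None:
            scfg = syn.SyntheticConfig(**{**cfg["synth"], "seed": seed})
            bundle, truth = syn.generate_cohort(scfg)
            syn.write_cohort(bundle, truth, out_dir / "cohort")
            record(stage, {"ground_truth": out_dir / "cohort" / "ground_truth.json"})
        elif cfg["data"] is not None:
            bundle = _load_bundle(cfg["data"])
            truth = None
        else:
            raise ValidationError("config must provide either 'synth' or 'data'")
    except Exception as exc:
        raise RuntimeError(
            f"stage {stage} failed (seed {seed}): {exc}; "
            f"reproduce with capdyn run --config <config> --seed {cfg['seed']}"
        ) from exc

    # ---- stage: cluster -------------------------------------------------
    stage = "cluster"
    seed = _stage_seed(cfg["seed"], stage)
    manifest.stage_seeds[stage] = seed
    ccfg = cfg["cluster"]
    normalized = [capio.normalize_subject(ts) for ts in bundle.subjects]
    dataset = capio.concatenate_cohort(normalized)
    input_key = _digest_obj({"cfg": ccfg, "seed": seed,
                             "data": hashlib.sha256(dataset.matrix.tobytes()).hexdigest()})
    manifest.stage_inputs[stage] = input_key
    cluster_files = ["labels.tsv", "centroids.tsv", "k_selection.csv", "radar.csv"]
    if cache_hit(stage, input_key, cluster_files):
        manifest.cached.append(stage)
        labels = np.loadtxt(out_dir / "labels.tsv", dtype=int)
        centroids = np.loadtxt(out_dir / "centroids.tsv")
        k_used = centroids.shape[0]
        for name in cluster_files:
            manifest.outputs[f"{stage}/{name}"] = _digest(out_dir / name)
    else:
        try:
            if ccfg.get("select", True):
                report = cl.scan_k(
                    dataset, k_min=ccfg["k_min"], k_max=ccfg["k_max"],
                    n_restarts=ccfg["n_restarts"], seed=seed,
                )
                selection = cl.select_k(report)
                k_used = selection.k
                solution = report.solutions[k_used]
                report.table.to_csv(out_dir / "k_selection.csv", index=False)
            else:
                k_used = int(ccfg["k"])
                solution = cl.kmedoids(
                    dataset, k_used, n_restarts=ccfg["n_restarts"], seed=seed
                )
                pd.DataFrame([{"k": k_used}]).to_csv(
                    out_dir / "k_selection.csv", index=False
                )
            labels = solution.labels
            centroids = solution.mean_centroids
            np.savetxt(out_dir / "labels.tsv", labels[None, :], fmt="%d", delimiter="\t")
            capio.write_matrix(out_dir / "centroids.tsv", centroids)
            radar = []
            for s in range(k_used):
                profile = cl.map_state_to_networks(
                    centroids[s], bundle.parcellation, roi_labels=dataset.roi_labels
                )
                profile.insert(0, "state", s + 1)
                radar.append(profile)
            pd.concat(radar).to_csv(out_dir / "radar.csv", index=False)
            record(stage, {name: out_dir / name for name in cluster_files})
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed (seed {seed}): {exc}") from exc

    # ---- stage: dynamics ------------------------------------------------
    stage = "dynamics"
    seed = _stage_seed(cfg["seed"], stage)
    manifest.stage_seeds[stage] = seed
    try:
        sequences = dy.sequences_from_solution(dataset, labels, k_used)
        summaries = [
            dy.summarize(s, normalization=cfg["dynamics"]["normalization"])
            for s in sequences
        ]
        dy.cohort_table(summaries).to_csv(out_dir / "dynamics.csv", index=False)
        dy.transition_table(summaries).to_csv(out_dir / "transitions.csv", index=False)
        record(stage, {"dynamics.csv": out_dir / "dynamics.csv",
                       "transitions.csv": out_dir / "transitions.csv"})
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed (seed {seed}): {exc}") from exc

    # ---- stage: null (optional) ----------------------------------------
    stage = "null"
    if cfg["null"].get("enabled", False):
        seed = _stage_seed(cfg["seed"], stage)
        manifest.stage_seeds[stage] = seed
        try:
            comparison = nulls.compare_cluster_quality(
                bundle.subjects, n_surrogates=cfg["null"]["n_surrogates"],
                k=k_used, seed=seed, mode=cfg["null"]["mode"],
            )
            payload = {
                key: (val.tolist() if isinstance(val, np.ndarray) else val)
                for key, val in comparison.items()
            }
            (out_dir / "null_comparison.json").write_text(json.dumps(payload, indent=2))
            record(stage, {"null_comparison.json": out_dir / "null_comparison.json"})
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed (seed {seed}): {exc}") from exc
    else:
        manifest.skipped.append(stage)

    # ---- stage: energy (optional) --------------------------------------
    stage = "energy"
    ecfg = cfg["energy"]
    have_connectomes = bool(getattr(bundle, "connectomes", None))
    if ecfg.get("enabled", True) and have_connectomes:
        seed = _stage_seed(cfg["seed"], stage)
        manifest.stage_seeds[stage] = seed
        try:
            rows = []
            per_subject = {}
            for conn in bundle.connectomes:
                system = ct.normalize_adjacency(conn, c=ecfg["norm_c"])
                totals, _ = ct.transition_energy_matrix(
                    system, centroids, horizon_T=ecfg["horizon"],
                    rho=ecfg["rho"], n_time_steps=ecfg["n_time_steps"],
                    state_scale=ecfg["state_scale"],
                )
                per_subject[conn.subject_id] = totals
                for i in range(k_used):
                    for j in range(k_used):
                        rows.append({
                            "subject": conn.subject_id, "from_state": i + 1,
                            "to_state": j + 1, "energy": totals[i, j],
                        })
            pd.DataFrame(rows).to_csv(out_dir / "energies.csv", index=False)
            landscape_rows = []
            for sid, totals in per_subject.items():
                land = ct.exit_enter_energies(totals)
                t = land.table
                t.insert(0, "subject", sid)
                landscape_rows.append(t)
            pd.concat(landscape_rows).to_csv(out_dir / "landscape.csv", index=False)
            record(stage, {"energies.csv": out_dir / "energies.csv",
                           "landscape.csv": out_dir / "landscape.csv"})
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed (seed {seed}): {exc}") from exc
    else:
        if ecfg.get("enabled", True):
            logger.warning("no connectomes available: energy stage skipped")
        manifest.skipped.append(stage)

    # ---- stage: infer ---------------------------------------------------
    stage = "infer"
    seed = _stage_seed(cfg["seed"], stage)
    manifest.stage_seeds[stage] = seed
    try:
        dyn = pd.read_csv(out_dir / "dynamics.csv")
        results = []
        for metric in ("dwell_time_s", "fractional_occupancy_pct",
                       "exit_probability", "enter_probability"):
            results.append(inf.group_metric_tests(
                dyn, bundle.clinical, metric, adjust=cfg["infer"]["adjust"]
            ))
        group_tests = pd.concat(results)
        group_tests.to_csv(out_dir / "group_tests.csv", index=False)

        reg_rows = []
        clin = bundle.clinical.table.set_index("subject")
        for score in cfg["infer"]["scores"]:
            if score not in clin.columns:
                continue
            for state, chunk in dyn.groupby("state"):
                chunk = chunk.set_index("subject")
                joined = chunk.join(clin, how="inner")
                for grp in ("HC", "MDD"):
                    sub = joined[joined["group"] == grp]
                    try:
                        reg = inf.ols_with_covariates(
                            sub["fractional_occupancy_pct"].to_numpy(),
                            sub[score].to_numpy(),
                            sub.reset_index(),
                        )
                    except ValidationError:
                        continue
                    reg_rows.append({
                        "score": score, "state": state, "group": grp,
                        "beta_cx": reg.coefficients["cx"],
                        "t_cx": reg.t_values["cx"],
                        "p_cx": reg.p_values["cx"],
                        "r_squared": reg.r_squared, "n": reg.n,
                    })
        pd.DataFrame(reg_rows).to_csv(out_dir / "regressions.csv", index=False)
        record(stage, {"group_tests.csv": out_dir / "group_tests.csv",
                       "regressions.csv": out_dir / "regressions.csv"})
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed (seed {seed}): {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out_dir / "manifest.json")
    return manifest


def _load_bundle(data_cfg: dict) -> syn.CohortBundle:
    """Load a cohort from disk (tab-delimited matrices + CSV tables)."""
    bold_dir = Path(data_cfg["bold_dir"])
    tr = float(data_cfg.get("tr", 1.0))
    subjects = [
        capio.read_matrix(p, kind="timeseries", tr_seconds=tr)
        for p in sorted(bold_dir.glob("*.tsv"))
    ]
    if not subjects:
        raise ValidationError(f"no BOLD matrices found in {bold_dir}")
    parcellation = capio.read_parcellation(data_cfg["parcellation"])
    clinical = capio.read_clinical(data_cfg["clinical"])
    connectomes = []
    conn_dir = data_cfg.get("connectome_dir")
    if conn_dir:
        connectomes = [
            capio.read_matrix(p, kind="connectome")
            for p in sorted(Path(conn_dir).glob("*.tsv"))
        ]
    roi_labels = parcellation.table["roi_label"].tolist()
    for ts in subjects:
        ts.roi_labels = roi_labels
    for conn in connectomes:
        conn.roi_labels = roi_labels
    return syn.CohortBundle(
        subjects=subjects, connectomes=connectomes,
        clinical=clinical, parcellation=parcellation,
    )
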