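"""End-to-end orchestration: ICC gate -> clustering grid -> ARI gate -> CI.

``run_pipeline`` executes the stages in order, persists every intermediate
as CSV/JSON under a run directory, and writes a deterministic
``manifest.json`` (config echo, library versions, per-stage counts, sha256
of every structured output).  Identical config + seed reproduce byte-
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from radrobust.composite import (
    DEFAULT_EPSILON,
    DEFAULT_MIN_CORR,
    DEFAULT_NEAR_WINNER_DELTA,
    DEFAULT_REDUNDANCY_CUTOFF,
    aggregate_winner_frequencies,
    composite_index,
    qc_filter,
    select_winners,
)
from radrobust.distances import ALL_METRICS
from radrobust.io import (
    AlignedPair,
    FeatureTable,
    align_platforms,
    read_feature_table,
    write_feature_table,
)
from radrobust.reliability import (
    DEFAULT_ICC_THRESHOLD,
    icc_results,
    filter_robust,
    load_repeated_measures_csv,
)
from radrobust.stability import (
    DEFAULT_ARI_THRESHOLD,
    evaluate_grid,
    select_stable_configs,
)
from radrobust.synthetic import (
    SimulationConfig,
    generate_platform_pair,
    generate_repeated_measures,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

DEFAULT_LINKAGES = ("ward.D2", "average", "complete", "single", "centroid")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for the exit summary."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # inputs: either file paths or a simulation block
    platform_a: str | None = None
    platform_b: str | None = None
    repeated_a: str | None = None
    repeated_b: str | None = None
    simulate: dict | None = None

    icc_threshold: float = DEFAULT_ICC_THRESHOLD
    icc_mode: str = "intersection"      # intersection | union | platform id
    allow_empty_icc: bool = False       # override: proceed with all features
    metrics: tuple[str, ...] = ALL_METRICS
    linkages: tuple[str, ...] = DEFAULT_LINKAGES
    k_range: tuple[int, int] = (2, 10)
    early_stop_threshold: float = 0.5
    early_stop_patience: int = 3
    k_policy: str = "consensus"
    ari_threshold: float = DEFAULT_ARI_THRESHOLD
    standardize_geometric: bool = True
    epsilon: float = DEFAULT_EPSILON
    near_winner_delta: float = DEFAULT_NEAR_WINNER_DELTA
    min_corr: float = DEFAULT_MIN_CORR
    redundancy_cutoff: float = DEFAULT_REDUNDANCY_CUTOFF
    make_plots: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("metrics", "linkages", "k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("metrics", "linkages", "k_range"):
            out[key] = list(out[key])
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_repeated_csv(rm, path: Path) -> None:
    rows = []
    for i, subj in enumerate(rm.subject_ids):
        for rep in range(rm.data.shape[1]):
            row = {"lesion_id": subj, "repetition": rep + 1}
            row.update(
                {f: rm.data[i, rep, j] for j, f in enumerate(rm.feature_names)}
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate is not None:
        sim = SimulationConfig(**{**cfg.simulate, "seed": cfg.seed})
        table_a, table_b, truth = generate_platform_pair(sim)
        rep_cfg_a = dataclasses.replace(sim, seed=cfg.seed)
        rep_cfg_b = dataclasses.replace(sim, seed=cfg.seed + 7)
        rm_a = generate_repeated_measures(rep_cfg_a)
        rm_b = generate_repeated_measures(rep_cfg_b)
        repeated = {"A": rm_a.per_feature(), "B": rm_b.per_feature()}
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(json.dumps({
            "block_of": truth.block_of,
            "robust_flags": truth.robust_flags,
            "applied_bias": truth.applied_bias,
            "applied_corruption": truth.applied_corruption,
        }, sort_keys=True, indent=1))
        return table_a, table_b, repeated
    if not (cfg.platform_a and cfg.platform_b):
        raise PipelineError("inputs", "need platform_a/platform_b paths or a simulate block")
    table_a, _ = read_feature_table(cfg.platform_a, "A")
    table_b, _ = read_feature_table(cfg.platform_b, "B")
    repeated = {}
    if cfg.repeated_a:
        repeated["A"] = load_repeated_measures_csv(cfg.repeated_a)
    if cfg.repeated_b:
        repeated["B"] = load_repeated_measures_csv(cfg.repeated_b)
    return table_a, table_b, repeated


def run_pipeline(cfg: PipelineConfig, outdir: str) -> Path:
    """Execute the full workflow; returns the run directory.

    Stage order: ICC filter -> alignment -> distance/clustering grid with
    consensus k -> ARI stability gate -> Composite Index + winner selection
    + QC per stable configuration -> winner-frequency aggregation.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    manifest: dict = {
        "config": cfg.to_dict(),
        "versions": _versions(),
        "summary": summary,
    }

    try:
        table_a, table_b, repeated = _load_inputs(cfg, out)
        summary["stages"]["inputs"] = {
            "n_lesions": [table_a.n_lesions, table_b.n_lesions],
            "n_features": [table_a.n_features, table_b.n_features],
        }

        # --- ICC gate -----------------------------------------------------
        if repeated:
            results = {
                pid: icc_results(meas, threshold=cfg.icc_threshold)
                for pid, meas in repeated.items()
            }
            for pid, res in results.items():
                pd.DataFrame(
                    [{"feature": r.feature_name, "icc": r.icc,
                      "category": r.category, "retained": r.retained}
                     for r in res]
                ).to_csv(out / f"icc_{pid}.csv", index=False)
            per_platform, retained = filter_robust(results, mode=cfg.icc_mode)
            summary["stages"]["icc"] = {
                "retained_per_platform": {p: len(v) for p, v in per_platform.items()},
                "retained_combined": len(retained),
                "threshold": cfg.icc_threshold,
                "mode": cfg.icc_mode,
            }
            if not retained:
                if not cfg.allow_empty_icc:
                    raise PipelineError(
                        "icc",
                        f"no feature passed ICC >= {cfg.icc_threshold}; "
                        "set allow_empty_icc to proceed with all features",
                    )
                retained = None  # override: keep everything
        else:
            retained = None
            summary["stages"]["icc"] = {"skipped": "no repeated measures provided"}

        # --- alignment ----------------------------------------------------
        pair = align_platforms(table_a, table_b)
        if retained is not None:
            keep = [f for f in pair.common_features if f in set(retained)]
            if len(keep) < 3:
                raise PipelineError(
                    "align", f"only {len(keep)} ICC-retained features shared"
                )
            pair = AlignedPair(
                pair.table_a.subset(feature_names=keep),
                pair.table_b.subset(feature_names=keep),
                keep, pair.report,
            )
        complete = [
            f for j, f in enumerate(pair.common_features)
            if np.all(np.isfinite(pair.table_a.values[:, j]))
            and np.all(np.isfinite(pair.table_b.values[:, j]))
        ]
        dropped_missing = sorted(set(pair.common_features) - set(complete))
        if dropped_missing:
            pair = AlignedPair(
                pair.table_a.subset(feature_names=complete),
                pair.table_b.subset(feature_names=complete),
                complete, pair.report,
            )
        write_feature_table(pair.table_a, out / "aligned_a.csv")
        write_feature_table(pair.table_b, out / "aligned_b.csv")
        (out / "alignment.json").write_text(json.dumps(
            {**pair.report.to_dict(), "dropped_missing": dropped_missing},
            sort_keys=True, indent=1,
        ))
        summary["stages"]["align"] = {
            "common_features": len(pair.common_features),
            "shared_lesions": pair.table_a.n_lesions,
            "dropped_missing": len(dropped_missing),
        }

        # --- stability grid ----------------------------------------------
        records = evaluate_grid(
            pair,
            metrics=cfg.metrics,
            linkages=cfg.linkages,
            k_policy=cfg.k_policy,
            k_range=cfg.k_range,
            early_stop=(cfg.early_stop_threshold, cfg.early_stop_patience),
            standardize=cfg.standardize_geometric,
        )
        stable = select_stable_configs(records, ari_threshold=cfg.ari_threshold)
        pd.DataFrame([r.to_row() for r in records]).to_csv(
            out / "grid.csv", index=False
        )
        summary["stages"]["grid"] = {
            "configurations": len(records),
            "errors": sum(r.error is not None for r in records),
            "stable": len(stable),
            "ari_threshold": cfg.ari_threshold,
        }
        if cfg.make_plots:
            from radrobust.plots import stability_scatter

            stability_scatter(records, "a", str(out / "stability_a.png"))
            stability_scatter(records, "b", str(out / "stability_b.png"))

        # --- composite index + winners per stable solution ----------------
        solutions = []
        solution_rows = []
        robustness_rows = []
        for rec in stable:
            part = rec.partition_a
            assert part is not None
            feats = [f for f in part.feature_names]
            ci_records = composite_index(pair, feats, epsilon=cfg.epsilon)
            selection = select_winners(
                part, ci_records, delta=cfg.near_winner_delta
            )
            idx = [pair.common_features.index(f) for f in feats]
            qc_filter(
                selection, ci_records, part,
                pair.table_a.values[:, idx], feats,
                min_corr=cfg.min_corr,
                redundancy_cutoff=cfg.redundancy_cutoff,
            )
            solutions.append(selection)
            config_id = f"{rec.metric}/{rec.linkage}/k={rec.k_a}"
            for r in ci_records:
                robustness_rows.append({"config": config_id, **r.to_row()})
            for cluster in sorted(selection.winners):
                solution_rows.append({
                    "config": config_id,
                    "cluster": cluster,
                    "winner": selection.winners[cluster],
                    "co_winners": ";".join(selection.co_winners[cluster]),
                    "near_winners": ";".join(selection.near_winners[cluster]),
                })
            for f in selection.final_set:
                solution_rows.append({
                    "config": config_id, "cluster": -1, "winner": f,
                    "co_winners": "final_set", "near_winners": "",
                })
        pd.DataFrame(
            robustness_rows,
            columns=["config", "feature", "r", "ks", "mfr", "mfr_sign",
                     "z_corr", "z_ks", "z_mfr", "ci"],
        ).to_csv(out / "robustness.csv", index=False)
        pd.DataFrame(
            solution_rows,
            columns=["config", "cluster", "winner", "co_winners", "near_winners"],
        ).to_csv(out / "solutions.csv", index=False)
        summary["stages"]["composite"] = {"solutions": len(solutions)}

        if solutions:
            freq = aggregate_winner_frequencies(solutions)
            pd.DataFrame(freq).to_csv(out / "winner_frequencies.csv", index=False)
            summary["stages"]["frequencies"] = {"features": len(freq)}
        else:
            summary["stages"]["frequencies"] = {
                "features": 0, "note": "no stable configuration at the ARI gate",
            }
    except PipelineError as exc:
        manifest["failed_stage"] = exc.stage
        manifest["error"] = str(exc)
        _finalize_manifest(manifest, out)
        raise

    _finalize_manifest(manifest, out)
    return out


def _versions() -> dict:
    import scipy
    import sklearn

    import radrobust

    return {
        "radrobust": radrobust.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _finalize_manifest(manifest: dict, out: Path) -> None:
    hashes = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in {".csv", ".json"} and p.name != "manifest.json"
    }
    manifest["output_sha256"] = hashes
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1)
    )
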