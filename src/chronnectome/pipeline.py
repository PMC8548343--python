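"""End-to-end analysis pipeline with a serialisable configuration.

Stages: simulate (or read) a cohort of component time courses →
post-process (detrend + low-pass) → tapered sliding-window sparse-
covariance FC per subject → two-stage L1 k-means states per candidate k
→ per-subject temporal metrics → meta-state metrics → group statistics
(GLM/LSD/d, Hotelling occupancy tests, TFNBS on state FC, optional
questionnaire correlations).  A single master seed fans out
deterministically to every random stage; rerunning with the same config
and seed reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import metastate as _metastate
from . import metrics as _metrics
from . import stats as _stats
from . import synthetic as _synthetic
from .io import SubjectTimecourses, postprocess_timecourses, read_cohort, read_maia
from .windows import WindowConfig, count_windows, fc_series, select_lambda

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline", "validate_against_truth"]


@dataclass
class SyntheticBlock:
    enabled: bool = True
    T: int = 235
    TR: float = 2.5
    n_components: int = 30


@dataclass
class ClusteringBlock:
    n_init: int = 10
    exemplar_mode: str = "variance_peaks"
    max_iter: int = 500
    split_half: bool = False
    n_random_sets: int = 5
    validity: bool = False
    validity_sample_size: int = 4000


@dataclass
class MetastateBlock:
    reference: str = "subject"
    loading_kind: str = "correlation"


@dataclass
class StatsBlock:
    tfnbs: bool = True
    tfnbs_E: float = 0.5
    tfnbs_H: float = 3.0
    tfnbs_dh: float | None = None
    n_permutations: int = 5000
    outlier_rule: str = "iqr_1p5"
    alpha: float = 0.05


@dataclass
class AnalysisConfig:
    """Full pipeline configuration; serialises losslessly to YAML."""

    seed: int = 0
    k_values: tuple[int, ...] = (2, 4)
    out_dir: str = "chronnectome-run"
    samplesheet: str | None = None
    maia: str | None = None
    postprocess: bool = True
    cutoff_hz: float = 0.15
    filter_order: int = 5
    # cohort-scale default: a short, well-conditioned penalty grid with a
    # handful of held-out splits (windows of 22 samples over 30 components
    # need lambda >= ~0.05 for a stable graphical-lasso fit)
    window: WindowConfig = field(
        default_factory=lambda: WindowConfig(
            lambda_grid=(0.05, 0.1, 0.15, 0.25), lambda_reps=5
        )
    )
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)
    clustering: ClusteringBlock = field(default_factory=ClusteringBlock)
    metastate: MetastateBlock = field(default_factory=MetastateBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        blocks = {
            "window": WindowConfig,
            "synthetic": SyntheticBlock,
            "clustering": ClusteringBlock,
            "metastate": MetastateBlock,
            "stats": StatsBlock,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in blocks:
                sub = blocks[key]
                known = {f.name for f in dataclasses.fields(sub)}
                unknown = set(val) - known
                if unknown:
                    raise ValueError(f"unknown keys in '{key}': {sorted(unknown)}")
                if "lambda_grid" in val:
                    val["lambda_grid"] = tuple(val["lambda_grid"])
                kwargs[key] = sub(**val)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = tuple(val) if key == "k_values" else val
            else:
                raise ValueError(f"unknown config key: '{key}'")
        return cls(**kwargs)

    def fingerprint(self) -> str:
        return hashlib.sha256(
            repr(dataclasses.asdict(self)).encode()
        ).hexdigest()[:16]


def _save_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _matrix_from_pairs(vec: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    M[iu] = vec
    return M + M.T


def _comparison_record(gc: _stats.GroupComparison) -> dict:
    return {
        "metric": gc.metric_name,
        "omnibus_F": gc.omnibus_F,
        "omnibus_p": gc.omnibus_p,
        "df": list(gc.df),
        "pairwise": {
            f"{a}-vs-{b}": v for (a, b), v in gc.pairwise.items()
        },
        "group_means": gc.group_means,
        "group_sds": gc.group_sds,
        "group_ns": gc.group_ns,
    }


def run_pipeline(config: AnalysisConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seed = int(config.seed)

    # ---------------- cohort ----------------
    truth = None
    if config.samplesheet:
        cohort = read_cohort(config.samplesheet)
    elif config.synthetic.enabled:
        states = _synthetic.default_states(config.synthetic.n_components)
        groups = _synthetic.default_groups()
        cohort, truth = _synthetic.simulate_cohort(
            groups, states, T=config.synthetic.T, TR=config.synthetic.TR,
            seed=seed,
        )
        truth.windowed(config.window.width_tr, config.window.step_tr)
        _synthetic.write_truth(truth, out / "truth.json")
    else:
        raise ValueError("no input: set samplesheet or enable synthetic block")
    logger.info("stage=cohort n=%d T=%d C=%d t=%.1fs", len(cohort),
                cohort[0].n_timepoints, cohort[0].n_components,
                time.time() - t0)
    if config.postprocess:
        cohort = [
            postprocess_timecourses(tc, config.cutoff_hz, config.filter_order)
            for tc in cohort
        ]
    group_of = {tc.subject_id: tc.group for tc in cohort}

    # ---------------- windowed FC ----------------
    n_w = count_windows(
        cohort[0].n_timepoints, config.window.width_tr, config.window.step_tr
    )
    cohort_fc = []
    for i, tc in enumerate(cohort):
        lam = select_lambda(tc, config.window, seed=seed + 10_000 + i)
        cohort_fc.append(fc_series(tc, config.window, lambda_penalty=lam))
    logger.info("stage=windowed_fc n_windows=%d P=%d t=%.1fs", n_w,
                cohort_fc[0].z_matrix.shape[1], time.time() - t0)
    _save_tsv(
        out / "lambda_per_subject.tsv",
        pd.DataFrame(
            {
                "subject_id": [fc.subject_id for fc in cohort_fc],
                "lambda": [fc.lambda_used for fc in cohort_fc],
            }
        ),
    )

    pooled = np.vstack([fc.z_matrix for fc in cohort_fc])
    summary = {
        "config_fingerprint": config.fingerprint(),
        "seed": seed,
        "n_subjects": len(cohort),
        "n_windows_per_subject": n_w,
        "n_pairs": pooled.shape[1],
        "pooled_instances": int(pooled.shape[0]),
        "k_results": {},
    }

    if config.clustering.validity:
        val = _cluster.cluster_validity(
            pooled, list(config.k_values), seed=seed + 15_000,
            n_init=config.clustering.n_init,
            max_iter=config.clustering.max_iter,
            sample_size=config.clustering.validity_sample_size,
        )
        (out / "validity.json").write_text(json.dumps(dataclasses.asdict(val)))

    maia = read_maia(config.maia) if config.maia else None

    # ---------------- per-k analyses ----------------
    for k in config.k_values:
        kdir = out / f"k{k}"
        kdir.mkdir(exist_ok=True)
        part = _cluster.two_stage_cluster(
            cohort_fc, k, exemplar_mode=config.clustering.exemplar_mode,
            n_init=config.clustering.n_init,
            max_iter=config.clustering.max_iter, seed=seed + 20_000 + k,
        )
        C = cohort[0].n_components
        cent = pd.DataFrame(
            np.vstack([
                _matrix_from_pairs(part.centroids[j], C).reshape(1, -1)
                for j in range(k)
            ])
        )
        cent.insert(0, "state", np.arange(1, k + 1))
        _save_tsv(kdir / "centroids_flat.tsv", cent)
        _save_tsv(
            kdir / "assignments.tsv",
            pd.DataFrame(
                {fc.subject_id: part.assignments[fc.subject_id]
                 for fc in cohort_fc}
            ),
        )

        # temporal metrics
        rows = []
        for fc in cohort_fc:
            m = _metrics.subject_state_metrics(
                fc.subject_id, part.assignments[fc.subject_id], k,
                tr_seconds=cohort[0].tr_seconds,
                step_tr=config.window.step_tr, group=group_of[fc.subject_id],
            )
            row = {"subject_id": m.subject_id, "group": m.group,
                   "n_transitions": m.n_transitions}
            for s in range(k):
                row[f"frac_state{s + 1}"] = m.fractional_windows[s]
                row[f"dwell_state{s + 1}_windows"] = m.mean_dwell_windows[s]
            rows.append(row)
        tm = pd.DataFrame(rows)
        _save_tsv(kdir / "temporal_metrics.tsv", tm)

        # meta-state metrics
        cohort_load = (
            _metastate.metastate_loadings(pooled, part.centroids,
                                          config.metastate.loading_kind)
            if config.metastate.reference == "cohort" else None
        )
        ms_rows = []
        for fc in cohort_fc:
            r = _metastate.metastate_result(
                fc, part.centroids, reference=config.metastate.reference,
                cohort_loadings=cohort_load,
                loading_kind=config.metastate.loading_kind,
            )
            ms_rows.append({
                "subject_id": r.subject_id, "group": r.group,
                "n_meta_states": r.n_meta_states, "n_changes": r.n_changes,
                "span": r.span, "total_distance": r.total_distance,
            })
        ms = pd.DataFrame(ms_rows)
        _save_tsv(kdir / "metastate_metrics.tsv", ms)

        # group statistics
        comparisons = []
        metric_cols = (
            ["n_transitions"]
            + [f"frac_state{s + 1}" for s in range(k)]
            + [f"dwell_state{s + 1}_windows" for s in range(k)]
        )
        for col in metric_cols:
            comparisons.append(_comparison_record(_stats.group_comparison(
                col, tm[col].to_numpy(), tm["group"].to_numpy()
            )))
        for col in ("n_meta_states", "n_changes", "span", "total_distance"):
            comparisons.append(_comparison_record(_stats.group_comparison(
                col, ms[col].to_numpy(dtype=float), ms["group"].to_numpy()
            )))

        occ_cols = [f"frac_state{s + 1}" for s in range(k)]
        occ_by_group = {
            g: tm.loc[tm["group"] == g, occ_cols].to_numpy()
            for g in sorted(tm["group"].unique())
        }
        hotelling = {"pairwise": {}, "omnibus": {}}
        for a, b in itertools.combinations(sorted(occ_by_group), 2):
            T2, F, p = _stats.hotelling_t2(occ_by_group[a], occ_by_group[b])
            hotelling["pairwise"][f"{a}-vs-{b}"] = {"T2": T2, "F": F, "p": p}
        if len(occ_by_group) > 2:
            wl, F, p = _stats.hotelling_omnibus(occ_by_group)
            hotelling["omnibus"] = {"wilks_lambda": wl, "F": F, "p": p}

        tfnbs_reports = []
        if config.stats.tfnbs:
            for s in range(1, k + 1):
                per_group: dict[str, list[np.ndarray]] = {}
                skip = False
                for fc in cohort_fc:
                    mask = part.assignments[fc.subject_id] == s
                    if mask.any():
                        per_group.setdefault(
                            group_of[fc.subject_id], []
                        ).append(fc.z_matrix[mask].mean(axis=0))
                for a, b in itertools.combinations(sorted(per_group), 2):
                    if len(per_group[a]) < 2 or len(per_group[b]) < 2:
                        continue
                    rep = _stats.tfnbs(
                        np.vstack(per_group[a]), np.vstack(per_group[b]),
                        cohort_fc[0].pair_index, C,
                        n_permutations=config.stats.n_permutations,
                        E=config.stats.tfnbs_E, H=config.stats.tfnbs_H,
                        dh=config.stats.tfnbs_dh,
                        seed=seed + 40_000 + 100 * k + s, state=s,
                        group_pair=(a, b),
                    )
                    tfnbs_reports.append({
                        "state": s, "group_pair": [a, b],
                        "n_permutations": rep.n_permutations,
                        "seed": rep.seed, "params": rep.params,
                        "min_fwe_p": float(rep.fwe_p.min()),
                        "n_significant": int(
                            (rep.fwe_p < config.stats.alpha).sum()
                        ),
                        "max_abs_t": float(np.abs(rep.edge_t).max()),
                    })

        maia_corr = []
        if maia is not None:
            merged = tm.merge(ms, on=["subject_id", "group"])
            merged = merged.merge(
                maia, left_on="subject_id", right_index=True, how="inner"
            )
            for g in sorted(merged["group"].unique()):
                sub = merged[merged["group"] == g]
                for metric in metric_cols + ["n_meta_states", "n_changes",
                                             "span", "total_distance"]:
                    for dim in maia.columns:
                        x = sub[metric].to_numpy(dtype=float)
                        y = sub[dim].to_numpy(dtype=float)
                        keep = _stats.outlier_screen(
                            x, config.stats.outlier_rule
                        ) if np.isfinite(x).all() else np.arange(x.size)
                        try:
                            rho, p = _stats.spearman(x[keep], y[keep])
                        except ValueError:
                            continue
                        maia_corr.append({
                            "group": g, "metric": metric, "maia_dim": dim,
                            "rho": rho, "p": p,
                            "n": int(keep.size),
                        })

        report = {
            "k": k,
            "inertia": part.inertia,
            "config_fingerprint": config.fingerprint(),
            "comparisons": comparisons,
            "hotelling": hotelling,
            "tfnbs": tfnbs_reports,
            "maia_correlations": maia_corr,
        }
        (kdir / "group_stats.json").write_text(json.dumps(report, indent=1))

        if config.clustering.split_half:
            rep = _cluster.split_half_reproducibility(
                cohort_fc, k, n_random_sets=config.clustering.n_random_sets,
                exemplar_mode=config.clustering.exemplar_mode,
                n_init=config.clustering.n_init, seed=seed + 30_000 + k,
            )
            (kdir / "split_half.json").write_text(json.dumps(rep))

        summary["k_results"][str(k)] = {
            "inertia": part.inertia,
            "pooled_state_counts": {
                str(s): int((part.pooled_labels() == s).sum())
                for s in range(1, k + 1)
            },
        }
        logger.info("stage=k%d done t=%.1fs", k, time.time() - t0)

    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    manifest = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete t=%.1fs", time.time() - t0)
    return out


def _match_labels(pred: np.ndarray, true: np.ndarray, k: int):
    """Best label permutation (applied to pred) and its accuracy."""
    best_perm, best_acc = None, -1.0
    for perm in itertools.permutations(range(1, k + 1)):
        mapped = np.asarray(perm)[pred - 1]
        acc = float((mapped == true).mean())
        if acc > best_acc:
            best_acc, best_perm = acc, perm
    return best_perm, best_acc


def validate_against_truth(
    partition: _cluster.StatePartition,
    truth: _synthetic.SyntheticTruth,
    states: list | None = None,
    fc_by_subject: dict[str, np.ndarray] | None = None,
) -> dict:
    """Score a state partition against the simulator's hidden truth.

    Reports window-level assignment accuracy after optimal label
    matching, per-group occupancy estimation error, and (when the
    generating ``states`` are given) the Pearson correlation between each
    matched centroid and the true state's Fisher-z connectivity vector.
    """
    from .windows import fisher_z

    sids = list(partition.assignments)
    missing = [s for s in sids if s not in truth.window_state_sequence]
    if missing:
        raise ValueError(f"truth lacks window labels for {missing[:3]}")
    pred = np.concatenate([partition.assignments[s] for s in sids])
    true = np.concatenate([truth.window_state_sequence[s] for s in sids])
    if pred.shape != true.shape:
        raise ValueError("truth/run shape mismatch")
    k = partition.k
    perm, acc = _match_labels(pred, true, k)

    report: dict = {
        "assignment_accuracy": acc,
        "label_permutation": list(perm),
    }

    if states is not None:
        iu = np.triu_indices(states[0].covariance.shape[0], k=1)
        true_vecs = []
        for st in states:
            d = np.sqrt(np.diag(st.covariance))
            R = st.covariance / np.outer(d, d)
            true_vecs.append(fisher_z(R[iu]))
        corrs = {}
        for s in range(1, k + 1):
            # centroid with predicted label s maps to true state perm[s-1]
            t_idx = perm[s - 1] - 1
            if t_idx < len(true_vecs):
                c = np.corrcoef(partition.centroids[s - 1], true_vecs[t_idx])[0, 1]
                corrs[f"state{perm[s - 1]}"] = float(c)
        report["centroid_truth_correlation"] = corrs

    # per-group occupancy error (mean abs difference of group-mean occupancy)
    groups = sorted(set(truth.group_of.values()))
    occ_err = {}
    for g in groups:
        gs = [s for s in sids if truth.group_of[s] == g]
        if not gs:
            continue
        est = np.mean(
            [
                _metrics.fractional_windows(
                    np.asarray(perm)[partition.assignments[s] - 1], k
                )
                for s in gs
            ],
            axis=0,
        )
        tru = np.mean(
            [
                _metrics.fractional_windows(truth.window_state_sequence[s], k)
                for s in gs
            ],
            axis=0,
        )
        occ_err[g] = float(np.abs(est - tru).max())
    report["group_occupancy_error"] = occ_err
    return report
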