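"""Metrics, the bias-gap protocol, ligand-stability statistics and splits.

Regression quality is summarised by Pearson's R and RMSE (pK units);
ranking quality by Spearman's rho, both over the whole test set and as an
unweighted mean over manifest clusters (CASF-style per-target groups).
Undefined correlations (zero variance, too few points) are reported as
missing (NaN), never as 0.

The bias gap dR compares the mean test correlation of models trained on the
full complex with that of models trained on only one partner; a small gap
means the model was not really using the interaction.  Ligand stability is
the maximum ligand RMSD along a replicate simulation after superposing each
frame's pocket onto the first frame; a replicate is "stable" when that
maximum stays below a threshold (2 Å by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.transform import Rotation as ScipyRotation

from .datatypes import Manifest, Trajectory
from .errors import GridbindError


def pearson_r(pred, truth) -> float:
    """Pearson correlation; NaN when undefined (n < 2 or zero variance)."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    _check_paired(pred, truth)
    if np.std(pred) == 0 or np.std(truth) == 0:
        return float("nan")
    return float(stats.pearsonr(pred, truth).statistic)


def rmse(pred, truth) -> float:
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    _check_paired(pred, truth)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def spearman(pred, truth) -> float:
    """Spearman rank correlation with average-tie ranks; NaN when undefined."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    _check_paired(pred, truth)
    if np.std(pred) == 0 or np.std(truth) == 0:
        return float("nan")
    return float(stats.spearmanr(pred, truth).statistic)


def _check_paired(pred, truth) -> None:
    if pred.shape != truth.shape or pred.ndim != 1:
        raise GridbindError(f"pred and truth must be matching 1-D arrays, got "
                            f"{pred.shape} and {truth.shape}")
    if len(pred) < 2:
        raise GridbindError("metrics need at least 2 paired values")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise GridbindError("metrics need finite values")


@dataclass
class MetricsReport:
    pearson_r: float
    rmse_pk: float
    spearman_all: float
    spearman_cluster_mean: float
    n_complexes: int
    per_cluster: pd.DataFrame
    flagged_clusters: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"pearson_r": self.pearson_r, "rmse_pk": self.rmse_pk,
                "spearman_all": self.spearman_all,
                "spearman_cluster_mean": self.spearman_cluster_mean,
                "n_complexes": self.n_complexes,
                "per_cluster": self.per_cluster.to_dict(orient="records"),
                "flagged_clusters": list(self.flagged_clusters)}


def spearman_per_cluster(per_complex_pred: pd.Series, manifest: Manifest) -> tuple[pd.DataFrame, float, list]:
    """Spearman rho per manifest cluster and its unweighted mean.

    Clusters with fewer than 2 predicted complexes are excluded from the mean
    and returned as flagged; if every cluster is a singleton this is an error.
    """
    clusters = manifest.clusters()
    labels = manifest.labels()
    rows, flagged = [], []
    by_cluster: dict[str, list[str]] = {}
    for cid in per_complex_pred.index:
        by_cluster.setdefault(clusters[cid], []).append(cid)
    for cl in sorted(by_cluster):
        members = by_cluster[cl]
        if len(members) < 2:
            flagged.append(cl)
            continue
        rho = spearman([per_complex_pred[c] for c in members],
                       [labels[c] for c in members])
        rows.append({"cluster_id": cl, "n": len(members), "spearman": rho})
    if not rows:
        raise GridbindError("every cluster is a singleton; per-cluster Spearman undefined")
    table = pd.DataFrame(rows, columns=["cluster_id", "n", "spearman"])
    mean = float(np.nanmean(table["spearman"].to_numpy()))
    return table, mean, flagged


def compute_metrics(per_complex_pred: pd.Series, manifest: Manifest) -> MetricsReport:
    """Full metrics report for per-complex predictions against manifest labels."""
    labels = manifest.labels()
    missing = [c for c in per_complex_pred.index if c not in labels]
    if missing:
        raise GridbindError(f"predictions for complexes not in the manifest: {missing[:5]}")
    truth = np.array([labels[c] for c in per_complex_pred.index])
    pred = per_complex_pred.to_numpy(dtype=float)
    table, cluster_mean, flagged = spearman_per_cluster(per_complex_pred, manifest)
    return MetricsReport(pearson_r(pred, truth), rmse(pred, truth),
                         spearman(pred, truth), cluster_mean,
                         len(per_complex_pred), table, flagged)


@dataclass
class BiasGapReport:
    mean_r_complex: float
    mean_r_ablated: float
    delta_r: float
    ablation: str
    n_model_replicates: int


def bias_gap(rs_complex, rs_ablated, ablation: str = "ligand_only") -> BiasGapReport:
    """dR = mean(per-replicate R, full complex) - mean(per-replicate R, ablated)."""
    rs_complex = list(map(float, rs_complex))
    rs_ablated = list(map(float, rs_ablated))
    if not rs_complex or not rs_ablated:
        raise GridbindError("bias_gap needs at least one correlation per condition")
    mc, ma = float(np.mean(rs_complex)), float(np.mean(rs_ablated))
    return BiasGapReport(mc, ma, mc - ma, ablation,
                         min(len(rs_complex), len(rs_ablated)))


def _superpose(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid least-squares fit of ``mov`` onto ``ref`` (Kabsch); returns
    (rotation matrix, ref centroid, mov centroid)."""
    ref_c, mov_c = ref.mean(axis=0), mov.mean(axis=0)
    rot, _ = ScipyRotation.align_vectors(ref - ref_c, mov - mov_c)
    return rot.as_matrix(), ref_c, mov_c


def ligand_max_rmsd(traj: Trajectory) -> float:
    """Maximum ligand RMSD (Å) along the trajectory, relative to frame 0.

    Each frame is first superposed on the pocket heavy atoms of frame 0
    (rigid least squares), which removes global rigid motion and isolates
    ligand movement within the binding site; the ligand-atom RMSD against
    frame 0 is then computed per frame and the maximum over frames >= 1 is
    returned.  With fewer than 3 pocket atoms no superposition is applied.
    """
    if traj.n_frames < 2:
        raise GridbindError("ligand_max_rmsd needs at least 2 frames")
    roles = np.array([a.role for a in traj.topology])
    lig, prot = roles == "ligand", roles == "protein"
    if not lig.any():
        raise GridbindError(f"complex {traj.complex_id!r}: no ligand atoms")
    ref_prot = traj.coords[0][prot]
    ref_lig = traj.coords[0][lig]
    worst = 0.0
    for t in range(1, traj.n_frames):
        frame = traj.coords[t]
        if prot.sum() >= 3:
            rot, ref_c, mov_c = _superpose(ref_prot, frame[prot])
            lig_t = (frame[lig] - mov_c) @ rot.T + ref_c
        else:
            lig_t = frame[lig]
        worst = max(worst, float(np.sqrt(np.mean(np.sum((lig_t - ref_lig) ** 2, axis=1)))))
    return 0.0 if worst < 1e-12 else worst  # snap superposition round-off to zero


@dataclass
class StabilityReport:
    max_rmsd: pd.DataFrame          # complex_id, replicate_id, max_rmsd_A, stable
    threshold_A: float
    affinity_split_pk: float
    fraction_stable_low: float      # NaN when the class is empty
    fraction_stable_high: float

    def to_dict(self) -> dict:
        return {"threshold_A": self.threshold_A,
                "affinity_split_pk": self.affinity_split_pk,
                "fraction_stable_low": self.fraction_stable_low,
                "fraction_stable_high": self.fraction_stable_high,
                "per_replicate": self.max_rmsd.to_dict(orient="records")}


def stability_fractions(trajectories: dict[str, list[Trajectory]],
                        labels: dict[str, float], threshold_A: float = 2.0,
                        affinity_split_pk: float | None = None) -> StabilityReport:
    """Fraction of stable ligands in low- vs high-affinity complexes.

    A replicate is stable iff its maximum ligand RMSD is below ``threshold_A``
    (strict).  Per-complex stability is the fraction of stable replicates;
    the low/high fractions average those per-complex values over complexes
    below / at-or-above the affinity boundary (dataset median pK by default).
    An empty affinity class yields NaN.
    """
    rows = []
    per_complex = {}
    for cid in sorted(trajectories):
        stables = []
        for traj in trajectories[cid]:
            m = ligand_max_rmsd(traj)
            stable = m < threshold_A
            stables.append(stable)
            rows.append({"complex_id": cid, "replicate_id": traj.replicate_id,
                         "max_rmsd_A": m, "stable": stable})
        if stables:
            per_complex[cid] = float(np.mean(stables))
    if not per_complex:
        raise GridbindError("no trajectories to analyse")
    labs = {c: labels[c] for c in per_complex}
    if affinity_split_pk is None:
        affinity_split_pk = float(np.median(list(labs.values())))
    low = [per_complex[c] for c, l in labs.items() if l < affinity_split_pk]
    high = [per_complex[c] for c, l in labs.items() if l >= affinity_split_pk]
    f_low = float(np.mean(low)) if low else float("nan")
    f_high = float(np.mean(high)) if high else float("nan")
    return StabilityReport(pd.DataFrame(rows), threshold_A, affinity_split_pk, f_low, f_high)


def leave_family_out_split(manifest: Manifest, family: str) -> tuple[Manifest, Manifest]:
    """Hold an entire protein family out as the test set.

    Returns ``(train_manifest, test_manifest)``: every complex of ``family``
    goes to test (split relabeled accordingly), everything else to train.
    """
    fams = manifest.families()
    if family not in fams:
        raise GridbindError(f"unknown protein family {family!r}; available: {fams}")
    t = manifest.table
    test = t[t["protein_family"] == family].copy()
    train = t[t["protein_family"] != family].copy()
    test["split"] = "test"
    train["split"] = "train"
    return Manifest(train), Manifest(test)
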