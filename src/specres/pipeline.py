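"""End-to-end orchestration: cluster -> encode -> importance -> IFS.

A single master seed deterministically derives every stage sub-seed, so
one integer reproduces a whole run. All intermediate tables are written
to the output directory, together with a run-metadata file recording
seeds, parameters, class balance and fold redraws, so any stage can be
re-run in isolation with identical results.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, encoding, forest, selection
from .io import EnzymePanel, read_panel, write_table


@dataclass
class RunConfig:
    """All stage parameters of a full run.

    Defaults follow the published analysis protocol: 500-tree forests,
    10 replicate classifiers, 10-fold cross-validation repeated 20
    times, FDR threshold 0.05.
    """

    alignment_path: str | None = None
    profiles_path: str | None = None
    out_dir: str = "specres_out"
    min_cluster_size: int = 4
    deep_split: int = 1
    n_trees: int = 500
    n_replicates: int = 10
    n_null_permutations: int = 100
    fdr_threshold: float = 0.05
    k_max: int | None = None  # default: number of significant positions
    folds: int = 10
    reps: int = 20
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def forest_config(self) -> forest.ForestConfig:
        return forest.ForestConfig(
            n_trees=self.n_trees,
            n_replicates=self.n_replicates,
            n_null_permutations=self.n_null_permutations,
            fdr_threshold=self.fdr_threshold,
        )


@dataclass
class RunResult:
    clusters: clustering.ClusterAssignment
    pca: clustering.PCADecomposition
    pairs: encoding.PairDataset
    importance: forest.ImportanceTable
    ifs: selection.IFSResult
    out_dir: Path


def run_all(config: RunConfig, panel: EnzymePanel | None = None) -> RunResult:
    """Execute the full analysis and write every intermediate artifact.

    ``panel`` may be passed directly (e.g. a synthetic panel); otherwise
    it is read from the configured alignment/profile paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config)}

    if panel is None:
        _stage = "io"
        try:
            panel = read_panel(config.alignment_path, config.profiles_path)
        except Exception as exc:
            raise RuntimeError(f"stage {_stage} failed: {exc}") from exc

    sub = forest.derive_seeds(config.seed, 3, "pipeline")
    control_seed, importance_seed, ifs_seed = (int(s) for s in sub)
    log["seeds"] = {
        "master": config.seed,
        "control": control_seed,
        "importance": importance_seed,
        "ifs": ifs_seed,
    }

    try:
        scaled = clustering.normalize_profiles(panel)
        clusters = clustering.cluster_enzymes(
            scaled, config.min_cluster_size, config.deep_split
        )
        pca = clustering.pca_variance(scaled, k=min(5, *panel.profiles.shape))
    except Exception as exc:
        raise RuntimeError(f"stage clustering failed: {exc}") from exc
    write_table(clusters.to_frame(), out / "clusters.tsv")
    (out / "linkage.nwk").write_text(
        clustering.linkage_to_newick(clusters.linkage, panel.enzyme_ids) + "\n"
    )
    write_table(
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(pca.variance_explained))],
                "variance_explained_pct": pca.variance_explained,
            }
        ),
        out / "pca_variance.tsv",
    )

    try:
        pairs = encoding.build_dataset(panel, clusters, control_seed)
    except Exception as exc:
        raise RuntimeError(f"stage encoding failed: {exc}") from exc
    write_table(pairs.to_frame(), out / "pairs.tsv")
    class_counts = clusters.labels.value_counts().sort_index()
    log["cluster_sizes"] = {int(k): int(v) for k, v in class_counts.items()}
    log["response_balance"] = {
        "between_cluster_pairs": int(pairs.response.sum()),
        "within_cluster_pairs": int(len(pairs.response) - pairs.response.sum()),
    }

    fc = config.forest_config()
    try:
        importance = forest.importance_scores(pairs, fc, importance_seed)
    except Exception as exc:
        raise RuntimeError(f"stage importance failed: {exc}") from exc
    write_table(importance.to_frame(), out / "importance.tsv")
    log["n_significant_positions"] = importance.n_significant

    try:
        ranking = selection.rank_positions(importance)
        if config.k_max:
            k_max = config.k_max
        elif importance.n_significant >= 2:
            k_max = importance.n_significant
        else:  # nothing cleared the FDR: scan a default-sized prefix
            k_max = 50
        k_max = max(2, min(k_max, len(ranking)))
        ifs = selection.ifs_curve(
            pairs, ranking, k_max, fc, ifs_seed, folds=config.folds, reps=config.reps
        )
        selection.mcc_plateau(ifs, alpha=config.alpha)
    except Exception as exc:
        raise RuntimeError(f"stage ifs failed: {exc}") from exc
    write_table(ifs.to_frame(), out / "ifs.tsv")
    write_table(
        pd.DataFrame(
            {
                "rank": range(1, len(ifs.plateau_positions) + 1),
                "position": ifs.plateau_positions,
            }
        ),
        out / "plateau_positions.tsv",
    )
    log["k_optimal"] = ifs.k_optimal
    log["k_plateau"] = ifs.k_plateau
    log["fold_redraws"] = ifs.n_fold_redraws

    with open(out / "run_metadata.yml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)

    return RunResult(
        clusters=clusters, pca=pca, pairs=pairs, importance=importance, ifs=ifs, out_dir=out
    )
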