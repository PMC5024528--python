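"""End-to-end orchestration: files in, disparity tables out.

Stage order is fixed: read and validate inputs, GPA, PCA, time-calibrate
the tree, reconstruct ancestral PC scores, bin all taxa and ancestors,
compute per-group disparity curves, then run the significance tests
(adjacent-bin and within-bin permutation disparity tests, NPMANOVA,
Bonferroni, disparity-vs-sample-size correlations).  Runs are deterministic
under the configured seed; every output is a flat text table and a manifest
records the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .chronophylo import calibrate_tree, midpoint_age, node_ages, ancestral_pc_scores
from .disparity import (
    assign_bins,
    bonferroni,
    disparity_curve,
    disparity_size_correlation,
    group_membership_sets,
    npmanova,
    permutation_disparity_test,
)
from .ordination import ShapePCA, broken_stick
from .superimposition import GeneralizedProcrustes

logger = logging.getLogger("morphodtt")

__all__ = ["RunConfig", "run_full_analysis", "relabel_groups"]


@dataclass
class RunConfig:
    """Paths and parameters of a full run.

    ``n_pcs`` is either a fixed count or ``"broken-stick"`` to let the
    broken-stick rule choose the retained block.  ``groups`` may be omitted,
    in which case group labels come from the age table's ``group`` column.
    ``composite_groups`` maps extra group names to the base groups they
    span (e.g. a crown group spanning its two subclades); an ``all`` group
    over every base label is always added.
    """

    tps: str
    tree: str
    ages: str
    bins: str
    out_dir: str
    groups: str | None = None
    n_pcs: int | str = 8
    min_taxa: int = 3
    min_branch_length: float = 0.1
    n_permutations: int = 10_000
    seed: int = 0
    include_ancestors: bool = True
    weighted_scp: bool = True
    composite_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr in ("tps", "tree", "ages", "bins", "groups"):
            path = getattr(self, attr)
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"{attr} path not readable: {path}")
        for attr in ("min_taxa", "min_branch_length", "n_permutations"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if isinstance(self.n_pcs, str) and self.n_pcs != "broken-stick":
            raise ValueError("n_pcs must be an integer or 'broken-stick'")


def relabel_groups(groups: dict[str, str], new_labels: dict[str, str]) -> dict[str, str]:
    """Reassign taxa to groups; shapes, tree and ages are untouched.

    ``new_labels`` maps taxa to their new group; every taxon it mentions
    must already exist in ``groups``.
    """
    unknown = sorted(set(new_labels) - set(groups))
    if unknown:
        raise mio.ValidationError(f"relabel map mentions unknown taxa: {unknown}")
    return {**groups, **new_labels}


def _comparison_seed(base_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([base_seed, index]))


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle to ``out_dir``.

    Returns a dict with the in-memory objects of each stage (``gpa``,
    ``pca``, ``scores``, ``tree``, ``ancestors``, ``bin_assignment``,
    ``curve``, ``tests``, ``npmanova``, ``correlations``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "io"
    try:
        configs = mio.read_tps(config.tps)
        tree = mio.read_newick(config.tree)
        ages = mio.read_age_table(config.ages)
        bins = mio.read_bin_table(config.bins)
        groups = (
            mio.read_group_table(config.groups)
            if config.groups
            else dict(zip(ages["taxon"], ages["group"]))
        )
        mio.validate_dataset(configs, tree, ages)
        missing = sorted(
            {leaf.taxon.label for leaf in tree.leaf_node_iter()} - set(groups)
        )
        if missing:
            raise mio.ValidationError(f"tree tips without a group: {missing}")
        logger.info(
            "io: %d configurations, %d tree tips, %d bins",
            len(configs),
            len(tree.taxon_namespace),
            len(bins),
        )

        stage = "gpa"
        gpa_est = GeneralizedProcrustes().fit(configs)
        residuals = (gpa_est.aligned_ - gpa_est.mean_).reshape(len(configs), -1)
        taxa = [c.taxon for c in configs]
        logger.info("gpa: converged in %d iterations", gpa_est.n_iter_)

        stage = "pca"
        pca_est = ShapePCA().fit(residuals)
        if config.n_pcs == "broken-stick":
            m = max(1, broken_stick(pca_est.explained_variance_))
        else:
            m = int(config.n_pcs)
        m = min(m, pca_est.scores_.shape[1])
        scores = pd.DataFrame(
            pca_est.scores_[:, :m],
            index=taxa,
            columns=[f"PC{i + 1}" for i in range(m)],
        )
        logger.info(
            "pca: retaining %d PCs (%.1f%% of variance)",
            m,
            100 * pca_est.explained_variance_ratio_[:m].sum(),
        )

        stage = "calibrate"
        tip_mid = {
            row.taxon: midpoint_age(row.fad, row.lad) for row in ages.itertuples()
        }
        cal_tree = calibrate_tree(tree, tip_mid, min_bl=config.min_branch_length)

        stage = "ancestors"
        tip_labels = [n.taxon.label for n in cal_tree.leaf_node_iter()]
        anc_scores, _cost = ancestral_pc_scores(
            cal_tree, scores.loc[tip_labels], weighted=config.weighted_scp
        )

        stage = "bin"
        all_ages = node_ages(cal_tree)
        labels = list(tip_labels)
        frames = [scores.loc[tip_labels]]
        if config.include_ancestors:
            labels += list(anc_scores.index)
            frames.append(anc_scores)
        scores_all = pd.concat(frames)
        bin_assignment = assign_bins(
            {lab: all_ages[lab] for lab in labels}, bins
        )

        stage = "disparity"
        membership = group_membership_sets(
            groups, cal_tree if config.include_ancestors else None
        )
        base_groups = sorted(set(groups.values()))
        group_sets: dict[str, tuple[str, ...]] = {g: (g,) for g in base_groups}
        group_sets.update({k: tuple(v) for k, v in config.composite_groups.items()})
        group_sets["all"] = tuple(base_groups)
        bin_order = list(bins["name"])
        curve = disparity_curve(
            scores_all,
            bin_assignment,
            membership,
            group_sets,
            bin_order,
            m_pcs=m,
            min_taxa=config.min_taxa,
        )

        stage = "tests"
        members_by = {
            (g, b): [
                lab
                for lab in scores_all.index
                if lab in membership
                and (
                    frozenset([membership[lab]])
                    if isinstance(membership[lab], str)
                    else frozenset(membership[lab])
                )
                <= frozenset(group_sets[g])
                and bin_assignment.get(lab) == b
            ]
            for g in group_sets
            for b in bin_order
        }

        comparisons = []
        for g in group_sets:  # adjacent bins within each group
            for b1, b2 in zip(bin_order, bin_order[1:]):
                comparisons.append((f"{g}: {b1} vs {b2}", (g, b1), (g, b2)))
        for b in bin_order:  # group pairs within each bin
            names = list(group_sets)
            for i, g1 in enumerate(names):
                for g2 in names[i + 1 :]:
                    if set(group_sets[g1]) & set(group_sets[g2]):
                        continue  # skip overlapping/composite-vs-part pairs
                    comparisons.append((f"{b}: {g1} vs {g2}", (g1, b), (g2, b)))

        test_rows, np_rows = [], []
        for i, (name, key_a, key_b) in enumerate(comparisons):
            a = scores_all.loc[members_by[key_a]].to_numpy()
            b_ = scores_all.loc[members_by[key_b]].to_numpy()
            if a.shape[0] < config.min_taxa or b_.shape[0] < config.min_taxa:
                continue
            obs, p = permutation_disparity_test(
                a,
                b_,
                n_permutations=config.n_permutations,
                seed=_comparison_seed(config.seed, 2 * i),
                min_taxa=config.min_taxa,
            )
            test_rows.append(
                {
                    "comparison": name,
                    "n_a": a.shape[0],
                    "n_b": b_.shape[0],
                    "observed_diff": obs,
                    "p": p,
                }
            )
            res = npmanova(
                np.vstack([a, b_]),
                ["A"] * a.shape[0] + ["B"] * b_.shape[0],
                n_permutations=config.n_permutations,
                seed=_comparison_seed(config.seed, 2 * i + 1),
            )
            np_rows.append(
                {
                    "comparison": name,
                    "n_a": a.shape[0],
                    "n_b": b_.shape[0],
                    "F": res.f_statistic,
                    "p": res.p_value,
                }
            )
        tests = pd.DataFrame(
            test_rows, columns=["comparison", "n_a", "n_b", "observed_diff", "p"]
        )
        if len(tests):
            tests["p_adj"] = bonferroni(tests["p"])
        np_table = pd.DataFrame(np_rows, columns=["comparison", "n_a", "n_b", "F", "p"])
        if len(np_table):
            np_table["p_adj"] = bonferroni(np_table["p"])
        logger.info("tests: %d comparisons met the min-taxa rule", len(tests))

        corr_rows = []
        for g in group_sets:
            sub = curve[curve["group"] == g]
            try:
                rho, p = disparity_size_correlation(sub["sov"], sub["n"])
            except ValueError:
                continue
            corr_rows.append({"group": g, "spearman_rho": rho, "p": p})
        correlations = pd.DataFrame(corr_rows, columns=["group", "spearman_rho", "p"])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # outputs
    eig = pd.DataFrame(
        {
            "PC": [f"PC{i + 1}" for i in range(pca_est.explained_variance_.size)],
            "eigenvalue": pca_est.explained_variance_,
            "pct_variance": 100 * pca_est.explained_variance_ratio_,
        }
    )
    scores.to_csv(out / "ordination.tsv", sep="\t")
    eig.to_csv(out / "eigenvalues.tsv", sep="\t", index=False)
    mio.write_newick(cal_tree, out / "tree_calibrated.nwk")
    anc_scores.to_csv(out / "ancestors.tsv", sep="\t")
    curve.to_csv(out / "disparity.tsv", sep="\t", index=False)
    tests.to_csv(out / "tests.tsv", sep="\t", index=False)
    np_table.to_csv(out / "npmanova.tsv", sep="\t", index=False)
    correlations.to_csv(out / "correlation.tsv", sep="\t", index=False)

    cfg = dataclasses.asdict(config)
    cfg["composite_groups"] = {k: list(v) for k, v in cfg["composite_groups"].items()}
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "n_configurations": len(configs),
        "n_pcs_used": m,
        "pct_variance_used": float(
            100 * pca_est.explained_variance_ratio_[:m].sum()
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "gpa": gpa_est,
        "pca": pca_est,
        "scores": scores,
        "tree": cal_tree,
        "ancestors": anc_scores,
        "scores_all": scores_all,
        "bin_assignment": bin_assignment,
        "curve": curve,
        "tests": tests,
        "npmanova": np_table,
        "correlations": correlations,
        "n_pcs_used": m,
    }
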