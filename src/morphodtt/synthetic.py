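"""Synthetic studies with known ground truth for every pipeline stage.

A study is a dated fossil tree (all tips extinct, non-contemporaneous),
landmark configurations evolved along it by independent Brownian motion on
each coordinate, per-specimen nuisance similarity transforms (rotation,
translation, scaling — no reflection, matching the superimposition
contract), stratigraphic age ranges whose midpoints equal the true tip
ages, a stem/two-crown-subclade group partition, and equal-width time bins.
Everything is deterministic under the seed, and the ground-truth sidecar
(true node ages and configurations) suffices to score any stage exactly.

Defaults emulate the scale of the motivating study: 53 landmarks per
configuration (15 fixed + 38 semilandmarks), a few dozen taxa spread over a
few tens of Myr, and shape variance small relative to centroid size so the
data sit in the small-variation regime that Procrustes methods assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .chronophylo import _ensure_internal_labels, _label
from .io import LandmarkConfiguration, write_tps, write_newick

__all__ = [
    "reference_skull",
    "simulate_fossil_tree",
    "simulate_bm_landmarks",
    "apply_nuisance",
    "invert_nuisance",
    "SyntheticStudy",
    "generate_study",
]

N_FIXED_DEFAULT = 15
N_SEMI_DEFAULT = 38


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def reference_skull(n_landmarks: int = N_FIXED_DEFAULT + N_SEMI_DEFAULT) -> np.ndarray:
    """Deterministic ancestral template: an irregular elongate outline.

    Points lie on an ellipse (lateral-skull-like aspect ratio) with a
    harmonic modulation that breaks symmetry, so no pair of landmarks
    coincides and the shape has full rank.
    """
    theta = 2 * np.pi * np.arange(n_landmarks) / n_landmarks
    r = 1.0 + 0.18 * np.sin(3 * theta) + 0.09 * np.cos(5 * theta + 0.7)
    return np.column_stack([1.0 * r * np.cos(theta), 0.45 * r * np.sin(theta)])


def simulate_fossil_tree(
    n_tips: int,
    root_age: float,
    birth: float = 0.25,
    death: float = 0.12,
    seed=None,
    max_retries: int = 200,
) -> dendropy.Tree:
    """Forward birth-death tree with every tip an extinct, dated fossil.

    The process starts at ``root_age`` Ma with the root split and runs
    toward the present; dead lineages are kept as fossil tips.  Births stop
    once the prospective tip count reaches ``n_tips`` (conditioning on the
    sample size); lineages still alive at that point receive uniform
    extinction ages in (0, current time).  Realizations that go fully
    extinct with too few tips are retried.

    Returns a tree whose nodes carry ``.age`` (Ma) and whose edges carry
    lengths in Myr; tips are labelled ``t1..tn`` in birth order.
    """
    if n_tips < 3:
        raise ValueError("need n_tips >= 3")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    rng = _rng(seed)
    total_rate = birth + death
    for _ in range(max_retries):
        tree = dendropy.Tree()
        root = tree.seed_node
        root.age = float(root_age)
        active: list[dendropy.Node] = [root.new_child(), root.new_child()]
        n_done = 0
        t = root_age
        failed = False
        while len(active) + n_done < n_tips:
            if not active:
                failed = True
                break
            t -= rng.exponential(1.0 / (len(active) * total_rate))
            if t <= 0:
                # nobody died in time; cap remaining events above the present
                t = rng.uniform(0, min(a.parent_node.age for a in active)) * 0.5
            i = rng.integers(len(active))
            node = active.pop(i)
            node.age = float(t)
            if rng.random() < birth / total_rate:
                active.append(node.new_child())
                active.append(node.new_child())
            else:
                n_done += 1  # fossil tip
        if failed or len(active) + n_done != n_tips:
            continue
        for node in active:
            node.age = float(
                rng.uniform(0.05, 0.95) * min(t, node.parent_node.age)
            )
        # label tips in preorder
        k = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                k += 1
                node.taxon = tree.taxon_namespace.require_taxon(f"t{k}")
        _ensure_internal_labels(tree)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = node.parent_node.age - node.age
        tree.is_rooted = True
        return tree
    raise RuntimeError(
        f"could not simulate a {n_tips}-tip fossil tree in {max_retries} tries"
    )


def simulate_bm_landmarks(
    tree: dendropy.Tree,
    ancestor_config: np.ndarray,
    sigma2: float,
    seed=None,
) -> dict[str, np.ndarray]:
    """Evolve a landmark configuration by Brownian motion along the tree.

    Every coordinate evolves independently with increment variance
    ``sigma2 * branch_length``; the returned dict maps every node label
    (root, internal, tip) to its true configuration.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = _rng(seed)
    ancestor_config = np.asarray(ancestor_config, dtype=float)
    _ensure_internal_labels(tree)
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            val = ancestor_config.copy()
        else:
            sd = np.sqrt(sigma2 * node.edge.length)
            val = values[id(node.parent_node)] + rng.normal(
                0.0, sd, ancestor_config.shape
            )
        values[id(node)] = val
        out[_label(node)] = val
    return out


def apply_nuisance(
    coords: np.ndarray,
    angle: float,
    scale: float,
    translation: tuple[float, float],
) -> tuple[np.ndarray, dict]:
    """Similarity transform (rotate by ``angle`` rad, scale, translate).

    Returns the transformed coordinates and a transform record that
    :func:`invert_nuisance` undoes exactly.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    coords = np.asarray(coords, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, s], [-s, c]])
    transform = {"angle": float(angle), "scale": float(scale), "translation": tuple(map(float, translation))}
    return scale * coords @ R + np.asarray(translation, dtype=float), transform


def invert_nuisance(coords: np.ndarray, transform: dict) -> np.ndarray:
    """Undo :func:`apply_nuisance` given its transform record."""
    coords = np.asarray(coords, dtype=float)
    angle, scale = transform["angle"], transform["scale"]
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, s], [-s, c]])
    return (coords - np.asarray(transform["translation"])) @ R.T / scale


def _pick_crown(tree: dendropy.Tree, n_tips: int):
    """Deep internal node whose clade will play the crown group."""
    best, best_score = None, np.inf
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        size = sum(1 for _ in node.leaf_iter())
        if size < 6 or len(node.child_nodes()) < 2:
            continue
        score = abs(size - n_tips / 2)
        if score < best_score:
            best, best_score = node, score
    return best


@dataclass
class SyntheticStudy:
    """A complete synthetic study plus its ground truth."""

    tree: dendropy.Tree  # true dated tree (.age on nodes)
    true_configs: dict[str, np.ndarray]  # node label -> (k, 2)
    observed: list[LandmarkConfiguration]  # nuisance-transformed tips
    nuisance: dict[str, dict]  # taxon -> transform record
    ages: pd.DataFrame  # taxon, fad, lad, group
    groups: dict[str, str]
    bins: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def tip_ages(self) -> dict[str, float]:
        return {
            n.taxon.label: float(n.age) for n in self.tree.leaf_node_iter()
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the pipeline-ready bundle plus the ground-truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tps": out / "shapes.tps",
            "tree": out / "tree.nwk",
            "ages": out / "ages.tsv",
            "bins": out / "bins.tsv",
            "groups": out / "groups.tsv",
            "truth": out / "truth_nodes.tsv",
        }
        write_tps(paths["tps"], self.observed)
        write_newick(self.tree, paths["tree"])
        self.ages.to_csv(paths["ages"], sep="\t", index=False)
        self.bins.to_csv(paths["bins"], sep="\t", index=False)
        pd.DataFrame(
            {"taxon": list(self.groups), "group": list(self.groups.values())}
        ).to_csv(paths["groups"], sep="\t", index=False)
        rows = []
        for node in self.tree.preorder_node_iter():
            lab = _label(node)
            rows.append(
                {"node": lab, "age": float(node.age), "is_tip": node.is_leaf()}
                | {
                    f"c{i}": v
                    for i, v in enumerate(self.true_configs[lab].ravel())
                }
            )
        pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_study(
    n_tips: int = 40,
    root_age: float = 35.0,
    n_landmarks: int = N_FIXED_DEFAULT + N_SEMI_DEFAULT,
    sigma2: float = 2e-4,
    birth: float = 0.25,
    death: float = 0.12,
    n_bins: int = 6,
    age_uncertainty: float = 2.0,
    seed=None,
) -> SyntheticStudy:
    """Generate a full study with ground truth.

    ``sigma2`` is the per-coordinate Brownian rate per Myr on a template of
    centroid size ~3, putting tip shapes within a few percent Procrustes
    distance of the ancestor — small-variation morphometrics.  Age ranges
    are symmetric around the true tip age (width up to ``age_uncertainty``
    Myr), so midpoint ages recover the truth exactly.
    """
    rng = _rng(seed)
    tree = simulate_fossil_tree(
        n_tips, root_age, birth=birth, death=death, seed=rng
    )
    template = reference_skull(n_landmarks)
    true_configs = simulate_bm_landmarks(tree, template, sigma2, seed=rng)

    crown = _pick_crown(tree, n_tips)
    groups: dict[str, str] = {}
    crown_tips = set()
    if crown is not None:
        children = crown.child_nodes()
        first = {leaf.taxon.label for leaf in children[0].leaf_iter()}
        for leaf in crown.leaf_iter():
            lab = leaf.taxon.label
            crown_tips.add(lab)
            groups[lab] = "crownA" if lab in first else "crownB"
    for leaf in tree.leaf_node_iter():
        groups.setdefault(leaf.taxon.label, "stem")

    observed: list[LandmarkConfiguration] = []
    nuisance: dict[str, dict] = {}
    age_rows = []
    for leaf in tree.leaf_node_iter():
        taxon = leaf.taxon.label
        coords, transform = apply_nuisance(
            true_configs[taxon],
            angle=rng.uniform(0, 2 * np.pi),
            scale=rng.uniform(0.5, 2.0),
            translation=tuple(rng.uniform(-5, 5, 2)),
        )
        observed.append(LandmarkConfiguration(taxon=taxon, coords=coords))
        nuisance[taxon] = transform
        half = rng.uniform(0, age_uncertainty / 2)
        half = min(half, 0.9 * leaf.age) if leaf.age > 0 else 0.0
        age_rows.append(
            {
                "taxon": taxon,
                "fad": leaf.age + half,
                "lad": leaf.age - half,
                "group": groups[taxon],
            }
        )
    ages = pd.DataFrame(age_rows)

    edges = np.linspace(root_age, 0.0, n_bins + 1)
    bins = pd.DataFrame(
        {
            "name": [f"bin{i + 1}" for i in range(n_bins)],
            "older": edges[:-1],
            "younger": edges[1:],
        }
    )
    # widen the oldest bin so calibrated hypothetical ancestors slightly
    # older than the root still fall inside the binning scheme
    bins.loc[0, "older"] = root_age + 0.5 * root_age

    return SyntheticStudy(
        tree=tree,
        true_configs=true_configs,
        observed=observed,
        nuisance=nuisance,
        ages=ages,
        groups=groups,
        bins=bins,
        params={
            "n_tips": n_tips,
            "root_age": root_age,
            "n_landmarks": n_landmarks,
            "sigma2": sigma2,
            "birth": birth,
            "death": death,
            "n_bins": n_bins,
            "age_uncertainty": age_uncertainty,
        },
    )
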