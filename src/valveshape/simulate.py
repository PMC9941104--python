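"""Synthetic valve datasets with the study's assumed statistical structure.

The generator produces everything the analysis pipeline consumes — a TPS
file, a classifier CSV, a Newick tree and a ground-truth record — from a
single seed.  The generating model is:

* a Yule (pure-birth) phylogeny, height normalized to 1;
* Brownian motion of shape in the tangent space at a bean-shaped template
  (low-rank covariance: a few integrated directions carry the variance)
  and of log centroid size, along the tree;
* an allometric shape vector: every valve is shifted by beta x
  (log CS - mean log CS);
* a directional-asymmetry vector added as +d/2 to right and -d/2 to left
  valves (left valves are then mirrored, as a left valve is digitized in
  its own orientation);
* a sexual-dimorphism vector (+s/2 males, -s/2 females), individual-level
  noise, and fluctuating-asymmetry noise per valve;
* an arbitrary similarity transform (rotation/translation/pixel scale) per
  valve, emulating digitization from differently magnified images; the TPS
  SCALE record restores physical units.

Default magnitudes mirror the variance ratios of the reference study
(directional asymmetry ~55x and species ~46x the fluctuating-asymmetry
mean square in shape; modest sexual dimorphism; ~15% evolutionary
allometry).  All randomness flows from one seed through named substreams
(tree, structure, species, specimen, valve, digitization) so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .data import ClassifierTable, LandmarkConfiguration, LandmarkDataset
from .superimpose import centroid_size, resample_outline
from .trees import PhyloTree

_STREAMS = {"tree": 1, "structure": 2, "species": 3, "specimen": 4, "valve": 5,
            "digitization": 6}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[name]])


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Generator settings; defaults give 46 species x 4 specimens.

    Shape quantities live in the Procrustes tangent space at the template
    (unit centroid size), sizes on the log scale (physical units: um).
    """

    n_species: int = 46
    specimens_per_species: int = 4
    extra_specimen_species: int = 0  # this many species get a 5th specimen
    n_one_valved: int = 0  # individuals represented by the right valve only
    birth_rate: float = 1.0
    n_dorsal: int = 28
    n_ventral: int = 18
    shape_rank: int = 3
    shape_trace: float = 0.006  # total tangent variance per unit tree height
    shape_spectrum: tuple = (0.60, 0.25, 0.15)
    size_rate: float = 0.014  # variance of log CS per unit tree height
    mean_log_cs: float = math.log(500.0)  # ~0.5 mm valves
    allometry_fraction: float = 0.15  # target contrast-level variance fraction
    da_magnitude: float = 0.021  # |d|, Procrustes units
    da_size: float = -0.01  # log-CS offset of right valves (LV larger)
    sex_magnitude: float = 0.0065  # |s|, Procrustes units
    sex_size: float = 0.0
    sigma_ind: float = 0.001  # per-tangent-dim individual shape sd
    sigma_fa: float = 0.0028  # per-tangent-dim fluctuating-asymmetry sd
    sigma_ind_logcs: float = 0.005
    sigma_fa_logcs: float = 0.01
    rotation_range: float = math.pi  # digitization rotation ~ U(-r, r)
    translation_range: float = 200.0  # physical units
    pixel_scale_range: tuple = (0.5, 2.0)  # SCALE = units per pixel

    @property
    def k(self) -> int:
        return 2 + self.n_dorsal + self.n_ventral

    @property
    def beta_norm(self) -> float:
        """|beta| implied by the target contrast-level allometric fraction."""
        f = self.allometry_fraction
        if f <= 0:
            return 0.0
        if not f < 1:
            raise ValueError("allometry_fraction must be < 1")
        return math.sqrt(f / (1 - f) * self.shape_trace / self.size_rate)

    def __post_init__(self):
        if len(self.shape_spectrum) != self.shape_rank:
            raise ValueError("shape_spectrum length must equal shape_rank")
        if self.shape_rank > 2 * self.k - 4:
            raise ValueError("shape covariance rank exceeds tangent dimension 2k-4")
        if abs(sum(self.shape_spectrum) - 1) > 1e-9 and self.shape_trace > 0:
            raise ValueError("shape_spectrum must sum to 1")

    @classmethod
    def study_scale(cls, **overrides) -> "SimulationParams":
        """Preset mirroring the reference dataset's bookkeeping:
        46 species, 202 individuals (18 species with 5 specimens, 28 with
        4) and 386 valves (18 one-valved individuals)."""
        base = dict(
            n_species=46,
            specimens_per_species=4,
            extra_specimen_species=18,
            n_one_valved=18,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null(cls, **overrides) -> "SimulationParams":
        """All effect sizes and variances zero (digitization noise only)."""
        base = dict(
            shape_trace=0.0,
            shape_spectrum=(0.0, 0.0, 0.0),
            size_rate=0.0,
            allometry_fraction=0.0,
            da_magnitude=0.0,
            da_size=0.0,
            sex_magnitude=0.0,
            sex_size=0.0,
            sigma_ind=0.0,
            sigma_fa=0.0,
            sigma_ind_logcs=0.0,
            sigma_fa_logcs=0.0,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed=None,
    normalize_height: bool = True,
    label_format: str = "sp{:02d}",
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_species`` tips.

    Starting from the root's two daughter lineages, each next speciation
    waits an Exp(m x birth_rate) time (m = current lineage count) and
    splits a uniformly chosen lineage; after the last split one further
    waiting time elapses, so the tree is ultrametric.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    t = 0.0
    birth_time = {root: 0.0}
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [c1, c2]
    birth_time[c1] = birth_time[c2] = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        parent.edge.length = t - birth_time[parent]
        a, b = dendropy.Node(), dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        birth_time[a] = birth_time[b] = t
        active.extend([a, b])
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, leaf in enumerate(active):
        leaf.edge.length = t - birth_time[leaf]
    # deterministic tip labels in preorder
    idx = 1
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.taxon = taxon_ns.new_taxon(label_format.format(idx))
            idx += 1
    if normalize_height and t > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= t
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# template and tangent-space structure
# ---------------------------------------------------------------------------

def bean_template(n_dorsal: int = 28, n_ventral: int = 18, n_dense: int = 2000):
    """Ostracod-like valve outline, resampled to the anchor convention.

    A bean curve (flattened ventrally, domed dorsally) sampled densely,
    anchored at the most anterior and most posterior points, and resampled
    arc-length-equidistantly into 2 + n_dorsal + n_ventral landmarks.
    Returned centred with unit centroid size.
    """
    t = np.linspace(0, 2 * np.pi, n_dense, endpoint=False)
    x = np.cos(t)
    y = 0.52 * np.sin(t) * (1 + 0.35 * np.cos(t))
    y = np.where(y < 0, 0.35 * y, y)  # flatten the ventral margin
    pts = np.column_stack([x, y])
    i_ant = int(np.argmin(pts[:, 0]))
    i_post = int(np.argmax(pts[:, 0]))
    # orient so vertex order runs anterior -> dorsal -> posterior
    if pts[(i_ant + n_dense // 8) % n_dense, 1] < pts[i_ant, 1]:
        pts = pts[::-1]
        i_ant = n_dense - 1 - i_ant
        i_post = n_dense - 1 - i_post
    lm = resample_outline(pts, (i_ant, i_post), n_dorsal, n_ventral)
    lm = lm - lm.mean(axis=0)
    return lm / centroid_size(lm)


def similarity_basis(template_unit: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k x 4) of the similarity subspace at a shape:
    x/y translation, scaling (the shape itself), infinitesimal rotation."""
    k = template_unit.shape[0]
    flat = template_unit.ravel()
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack([-template_unit[:, 1], template_unit[:, 0]]).ravel()
    B = np.column_stack([tx, ty, flat, rot])
    Q, _ = np.linalg.qr(B)
    return Q


def tangent_basis(template_unit: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k x (2k-4)) of the tangent space at the template
    (orthogonal complement of the similarity subspace)."""
    Q = similarity_basis(template_unit)
    k2 = template_unit.size
    P = np.eye(k2) - Q @ Q.T
    evals, evecs = np.linalg.eigh(P)
    return evecs[:, evals > 0.5]


@dataclass
class EffectStructure:
    """Seed-derived directions: shape covariance, allometry, DA, sex."""

    tangent: np.ndarray  # (2k, 2k-4)
    shape_directions: np.ndarray  # (2k, r), orthonormal within tangent space
    beta: np.ndarray  # (2k,) allometric vector, norm = params.beta_norm
    da: np.ndarray  # (2k,) directional-asymmetry vector, norm = da_magnitude
    sex: np.ndarray  # (2k,) sexual-dimorphism vector


def effect_structure(
    template_unit: np.ndarray, params: SimulationParams, seed: int
) -> EffectStructure:
    rng = _stream(seed, "structure")
    T = tangent_basis(template_unit)
    dim = T.shape[1]
    G = rng.standard_normal((dim, params.shape_rank + 3))
    Q, _ = np.linalg.qr(G)  # orthonormal directions in tangent coordinates
    dirs = T @ Q[:, : params.shape_rank]
    beta = T @ Q[:, params.shape_rank] * params.beta_norm
    da = T @ Q[:, params.shape_rank + 1] * params.da_magnitude
    sex = T @ Q[:, params.shape_rank + 2] * params.sex_magnitude
    return EffectStructure(
        tangent=T, shape_directions=dirs, beta=beta, da=da, sex=sex
    )


# ---------------------------------------------------------------------------
# trait evolution and dataset assembly
# ---------------------------------------------------------------------------

def simulate_species_traits(
    tree: PhyloTree,
    params: SimulationParams,
    structure: EffectStructure,
    seed: int,
):
    """Brownian tip values: tangent-space shape deviation and log CS.

    Returns (shape_dev DataFrame n x 2k, log_cs Series), both indexed by
    species code.  The allometric shift is *not* included here; it is
    applied per valve from the realized valve log CS.
    """
    rng = _stream(seed, "species")
    r = params.shape_rank
    scales = np.sqrt(np.asarray(params.shape_spectrum) * params.shape_trace)
    dev: dict = {}
    logcs: dict = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            dev[node] = np.zeros(r)
            logcs[node] = params.mean_log_cs
            continue
        bl = float(node.edge.length)
        dev[node] = dev[node.parent_node] + math.sqrt(bl) * scales * rng.standard_normal(r)
        logcs[node] = logcs[node.parent_node] + math.sqrt(bl * params.size_rate) * rng.standard_normal()
    tips = [n for n in tree.tree.leaf_node_iter()]
    labels = [n.taxon.label for n in tips]
    shape_rows = np.vstack([structure.shape_directions @ dev[n] for n in tips])
    return (
        pd.DataFrame(shape_rows, index=labels),
        pd.Series([logcs[n] for n in tips], index=labels, name="log_cs"),
    )


@dataclass
class SimulatedDataset:
    """A complete synthetic study: data, metadata, tree and ground truth."""

    configurations: list
    classifier: ClassifierTable
    tree: PhyloTree
    truth: dict

    def dataset(self) -> LandmarkDataset:
        return LandmarkDataset(self.configurations, self.classifier)

    def write(self, out_dir):
        from . import io as vio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vio.write_tps(self.configurations, out / "valves.tps")
        vio.write_classifier(self.classifier, out / "classifier.csv")
        self.tree.write(out / "tree.nwk")
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def _clade_labels(tree: PhyloTree) -> dict:
    """Label tips A-D by the four grandchild subtrees of the root (the
    two basal clades each split in two), '' where the topology is shallower."""
    root = tree.root
    grandchildren = []
    for child in root.child_nodes():
        kids = child.child_nodes()
        grandchildren.extend(kids if kids else [child])
    labels = {}
    names = "ABCD"
    for i, g in enumerate(grandchildren[:4]):
        name = names[i] if len(grandchildren) == 4 else ""
        for leaf in g.leaf_iter():
            labels[leaf.taxon.label] = name
    for leaf in root.leaf_iter():
        labels.setdefault(leaf.taxon.label, "")
    return labels


def simulate_dataset(
    tree: PhyloTree | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate a full synthetic valve dataset (TPS-ready) plus truth record."""
    params = params or SimulationParams()
    if tree is None:
        tree = simulate_yule_tree(params.n_species, params.birth_rate,
                                  seed=_stream(seed, "tree"))
    species = tree.tip_labels
    if len(species) != params.n_species:
        raise ValueError("tree tip count does not match params.n_species")

    template = bean_template(params.n_dorsal, params.n_ventral)
    structure = effect_structure(template, params, seed)
    shape_dev, log_cs = simulate_species_traits(tree, params, structure, seed)

    rng_spec = _stream(seed, "specimen")
    rng_valve = _stream(seed, "valve")
    rng_dig = _stream(seed, "digitization")

    n_spec = {
        sp: params.specimens_per_species + (1 if i < params.extra_specimen_species else 0)
        for i, sp in enumerate(species)
    }
    total_ind = sum(n_spec.values())
    # one-valved individuals: spread deterministically across the roster
    one_valved_every = total_ind / params.n_one_valved if params.n_one_valved else None

    clades = _clade_labels(tree)
    configs: list[LandmarkConfiguration] = []
    rows = []
    T = structure.tangent
    dim = T.shape[1]
    ind_counter = 0
    one_valved_ids = set()
    if params.n_one_valved:
        step = total_ind / params.n_one_valved
        one_valved_ids = {int(round(i * step)) for i in range(params.n_one_valved)}
    for sp in species:
        for j in range(n_spec[sp]):
            ind_counter += 1
            sid = f"S{ind_counter:04d}"
            sex = "M" if j % 2 == 0 else "F"
            sgn = +1.0 if sex == "M" else -1.0
            ind_shape = (
                shape_dev.loc[sp].to_numpy()
                + sgn * structure.sex / 2.0
                + params.sigma_ind * (T @ rng_spec.standard_normal(dim))
            )
            ind_logcs = (
                log_cs[sp]
                + sgn * params.sex_size / 2.0
                + params.sigma_ind_logcs * rng_spec.standard_normal()
            )
            sides = ("right",) if (ind_counter - 1) in one_valved_ids else ("right", "left")
            for side in sides:
                ssgn = +1.0 if side == "right" else -1.0
                lc = (
                    ind_logcs
                    + ssgn * params.da_size / 2.0
                    + params.sigma_fa_logcs * rng_valve.standard_normal()
                )
                dev = (
                    ind_shape
                    + ssgn * structure.da / 2.0
                    + params.sigma_fa * (T @ rng_valve.standard_normal(dim))
                    + structure.beta * (lc - params.mean_log_cs)
                )
                coords = (template.ravel() + dev).reshape(-1, 2)
                coords = coords * math.exp(lc)  # physical units
                if side == "left":
                    cen = coords.mean(axis=0)
                    coords[:, 0] = 2 * cen[0] - coords[:, 0]
                # digitization similarity transform
                theta = rng_dig.uniform(-params.rotation_range, params.rotation_range)
                R = np.array(
                    [[math.cos(theta), -math.sin(theta)],
                     [math.sin(theta), math.cos(theta)]]
                )
                shift = rng_dig.uniform(
                    -params.translation_range, params.translation_range, size=2
                )
                pixel_scale = rng_dig.uniform(*params.pixel_scale_range)
                coords = coords @ R.T + shift
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=sid,
                        side=side,
                        coords=coords,
                        scale=pixel_scale,
                        species_code=sp,
                        sex=sex,
                    )
                )
            rows.append(
                {
                    "specimen_id": sid,
                    "species": sp,
                    "sex": sex,
                    "clade": clades.get(sp, ""),
                    "locality": f"loc{(ind_counter % 28) + 1:02d}",
                    "depth": "",
                }
            )
    classifier = ClassifierTable(pd.DataFrame(rows).set_index("specimen_id"))
    truth = {
        "seed": int(seed),
        "newick": tree.to_newick(),
        "template": template,
        "beta": structure.beta,
        "da_vector": structure.da,
        # expected right-minus-left shape difference: the explicit DA vector
        # plus the allometry-mediated effect of the side offset in log CS
        "da_shape_total": structure.da + structure.beta * params.da_size,
        "sex_vector": structure.sex,
        "shape_directions": structure.shape_directions,
        "species_log_cs": {sp: float(log_cs[sp]) for sp in species},
        "allometry_fraction": params.allometry_fraction,
        "n_individuals": total_ind,
        "n_valves": len(configs),
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(params).items()
        },
    }
    return SimulatedDataset(
        configurations=configs, classifier=classifier, tree=tree, truth=truth
    )
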