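"""Functional supertype definition from positively selected residues.

MHC alleles are grouped into supertypes by the physicochemical properties of
the residues inferred to be under positive selection (the putative
peptide-binding positions).  Each selected residue is replaced by its five
z-scale descriptors — z1 (hydrophobicity), z2 (steric bulk), z3 (polarity),
z4 and z5 (electronic effects) — and alleles are clustered DAPC-style:
principal components retaining a target share of the variance, k-means over
a range of cluster counts, cluster number chosen by BIC (smallest k whose
BIC is within delta of the minimum), and final assignments through a linear
discriminant projection of the retained components.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import AlleleCatalog, PopulationGenotypes

__all__ = [
    "load_z_descriptors",
    "DescriptorEncoding",
    "SupertypeModel",
    "encode_z_descriptors",
    "dapc_cluster",
    "FrequencyTable",
    "supertype_frequencies",
]


def load_z_descriptors() -> dict[str, np.ndarray]:
    """The embedded 20x5 amino-acid z-scale table."""
    with resources.files("immunopop.data").joinpath("z_descriptors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="residue")
    return {aa: row.to_numpy(dtype=float) for aa, row in df.iterrows()}


@dataclass
class DescriptorEncoding:
    allele_ids: list[str]
    sites: list[int]  # 1-based amino-acid positions, ascending
    matrix: np.ndarray  # (n_alleles, 5 * n_sites)

    @property
    def feature_names(self) -> list[str]:
        return [f"site{s}_z{z}" for s in self.sites for z in range(1, 6)]


@dataclass
class SupertypeModel:
    retained_components: int
    k: int
    bic_curve: list[tuple[int, float]]
    assignments: dict[str, str]
    cluster_centers: np.ndarray


def encode_z_descriptors(
    catalog: AlleleCatalog, selected_sites: Sequence[int] | set[int]
) -> DescriptorEncoding:
    """Concatenate z1..z5 for each selected residue of each allele.

    A gap residue at a selected site is encoded as the 5-dimensional zero
    vector (declared convention); any other unknown residue symbol is an
    error.
    """
    scales = load_z_descriptors()
    translations = catalog.translate()
    protein_length = len(next(iter(translations.values())))
    sites = sorted(int(s) for s in selected_sites)
    if not sites:
        raise ValueError("no selected sites given")
    if sites[0] < 1 or sites[-1] > protein_length:
        raise ValueError(
            f"selected sites must lie in [1, {protein_length}]"
        )
    rows = []
    for allele_id in catalog.ids:
        protein = translations[allele_id]
        vec = []
        for site in sites:
            residue = protein[site - 1]
            if residue == "-":
                vec.extend([0.0] * 5)
            elif residue in scales:
                vec.extend(scales[residue])
            else:
                raise ValueError(
                    f"allele {allele_id!r}: unknown residue {residue!r} at site {site}"
                )
        rows.append(vec)
    return DescriptorEncoding(
        allele_ids=catalog.ids, sites=sites, matrix=np.asarray(rows, dtype=float)
    )


def dapc_cluster(
    encoding: DescriptorEncoding,
    k_max: int = 10,
    variance_retained: float = 0.95,
    delta_bic: float = 2.0,
    seed: Optional[int] = None,
    scale: bool = False,
) -> SupertypeModel:
    """DAPC-style clustering of allele encodings.

    k-means is run for k = 1..k_max (25 seeded restarts each) on principal
    components retaining ``variance_retained`` of the variance;
    BIC(k) = n ln(W_k / n) + k d ln(n) with W_k the total within-cluster
    sum of squares and d the retained dimensionality (each cluster
    contributes one d-dimensional center), and the chosen k is the smallest
    within ``delta_bic`` of the minimum.  Final labels come from a linear
    discriminant projection.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    x = encoding.matrix
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two alleles")
    k_max = min(k_max, n)
    # center only: scaling to unit variance would compress between-cluster
    # separation on exactly the axes that carry it
    scaled = x - x.mean(axis=0)
    if scale:
        std = x.std(axis=0)
        std[std == 0.0] = 1.0
        scaled = scaled / std

    if np.allclose(scaled, 0.0):
        assignments = {a: "ST1" for a in encoding.allele_ids}
        return SupertypeModel(0, 1, [(1, 0.0)], assignments, np.zeros((1, 1)))

    pca = PCA(n_components=min(n - 1, scaled.shape[1]), random_state=0)
    components = pca.fit_transform(scaled)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cumvar, variance_retained) + 1)
    # keep at least a few axes: a one-dimensional retained space lets k-means
    # profitably bisect a single Gaussian cluster and inflate k
    n_keep = min(max(n_keep, 3), components.shape[1])
    components = components[:, :n_keep]

    rng = np.random.default_rng(seed)
    bic_curve: list[tuple[int, float]] = []
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            w_k = float(np.sum((components - components.mean(axis=0)) ** 2))
            labels_by_k[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                n_init=25,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(components)
            w_k = float(km.inertia_)
            labels_by_k[k] = km.labels_
        w_k = max(w_k, 1e-12)
        # spherical k-means BIC: k cluster centers in n_keep dimensions
        bic = n * np.log(w_k / n) + k * n_keep * np.log(n)
        bic_curve.append((k, float(bic)))

    bics = np.array([b for _, b in bic_curve])
    chosen_k = int(np.argmax(bics - bics.min() <= delta_bic) + 1)
    labels = labels_by_k[chosen_k]

    if chosen_k > 1 and n_keep >= 2:
        lda = LinearDiscriminantAnalysis()
        try:
            lda.fit(components, labels)
            labels = lda.predict(components)
        except Exception:
            pass  # degenerate within-class covariance: keep k-means labels

    # stable label naming by first appearance
    remap: dict[int, str] = {}
    final = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = f"ST{len(remap) + 1}"
        final.append(remap[lab])
    assignments = dict(zip(encoding.allele_ids, final))
    centers = np.vstack(
        [components[labels == lab].mean(axis=0) for lab in dict.fromkeys(labels)]
    )
    return SupertypeModel(
        retained_components=n_keep,
        k=chosen_k,
        bic_curve=bic_curve,
        assignments=assignments,
        cluster_centers=centers,
    )


@dataclass
class FrequencyTable:
    """Per-population class (allele or supertype) counts and frequencies."""

    counts: pd.DataFrame  # populations x classes, gene-copy counts

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)


def supertype_frequencies(
    genotypes: PopulationGenotypes,
    model: SupertypeModel,
    locus: str = "DAB",
) -> FrequencyTable:
    """Map allele copy counts through supertype assignments, per population."""
    supertype_names = sorted(set(model.assignments.values()), key=lambda s: int(s[2:]))
    rows = {}
    for population in genotypes.populations:
        counts = genotypes.allele_counts(population, locus)
        if not counts:
            continue
        row = dict.fromkeys(supertype_names, 0)
        for allele, c in counts.items():
            if allele not in model.assignments:
                raise ValueError(f"allele {allele!r} has no supertype assignment")
            row[model.assignments[allele]] += c
        rows[population] = row
    if not rows:
        raise ValueError("no typed populations")
    df = pd.DataFrame.from_dict(rows, orient="index")[supertype_names]
    return FrequencyTable(counts=df)
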