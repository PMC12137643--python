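"""SNP- and pedigree-based kinship, inbreeding, and network clustering.

All outputs are on the *relatedness* scale (twice the kinship coefficient;
equivalently the GRM scale): a non-inbred self is 1, parent-offspring is
0.5, and the diagonal equals 1 + F for an inbred individual.  Observed
conventions of orchard-crop panels — full-sib means near 0.6, sport/clone
pairs near 0.97, clustering thresholds near 0.45 — are coherent on this
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import GenotypeMatrix, PedigreeTable
from .array_design import render_percent

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    samples: list
    values: np.ndarray
    source: str  # "snp" | "pedigree"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.samples)):
            raise ValueError("kinship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("kinship matrix must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kinship matrix must be finite")

    def get(self, a, b) -> float:
        return float(self.values[self.samples.index(a), self.samples.index(b)])


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------

def grm(genotypes: GenotypeMatrix, method: str = "centered") -> KinshipMatrix:
    """Marker-based relatedness from centered dosages.

    ``centered`` (default): K = Z Z' / sum_k 2 p_k (1 - p_k) with Z the
    column-centered dosage matrix — the VanRaden estimator, whose diagonal
    estimates 1 + F and whose parent-offspring expectation is 0.5.
    ``standardized``: columns additionally scaled by sqrt(2 p q) and the
    normaliser becomes the marker count (GCTA-style).

    Monomorphic and all-missing variants are dropped; missing dosages are
    mean-imputed per variant before centering (keeps K positive
    semidefinite).
    """
    if genotypes.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    X = genotypes.dosages.copy()
    all_missing = np.all(np.isnan(X), axis=0)
    if all_missing.any():
        logger.warning("grm: dropping %d all-missing variants", all_missing.sum())
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    poly = ~all_missing & (p > 0) & (p < 1)
    X = X[:, poly]
    p = p[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic variants for GRM")
    nan_at = np.isnan(X)
    X[nan_at] = np.take(2 * p, np.where(nan_at)[1])
    Z = X - 2 * p
    het = 2 * p * (1 - p)
    if method == "centered":
        K = Z @ Z.T / het.sum()
    elif method == "standardized":
        K = (Z / np.sqrt(het)) @ (Z / np.sqrt(het)).T / len(p)
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    return KinshipMatrix(samples=list(genotypes.samples), values=K, source="snp")


# ---------------------------------------------------------------------------
# Pedigree kinship
# ---------------------------------------------------------------------------

def pedigree_kinship(pedigree: PedigreeTable, sport_value: float = 0.97) -> KinshipMatrix:
    """Expected relatedness from the pedigree by the recursive tabular
    method, with sport (clonal mutant) handling.

    Kinship coefficients phi follow the classic recursion in topological
    order — phi(i,i) = (1 + phi(s,d)) / 2, phi(i,j) = (phi(s,j) +
    phi(d,j)) / 2 — and the output is reported as relatedness 2 phi, so a
    founder self is 1.0 and parent-offspring is 0.5.  A sport copies its
    source cultivar's kinship row (it is a clone), and the sport-source
    pair itself is overridden to ``sport_value``, reflecting the near-but-
    not-exact identity of bud mutants.
    """
    order = pedigree.topological_order()
    idx = {s: i for i, s in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    parent_of = {}
    sport_of = dict(pedigree.sport_pairs())
    for _, row in pedigree.df.iterrows():
        parent_of[row["individual"]] = (row["sire"], row["dam"])

    for ind in order:
        i = idx[ind]
        if ind in sport_of:
            p = idx[sport_of[ind]]
            phi[i, :] = phi[p, :]
            phi[:, i] = phi[:, p]
            phi[i, i] = phi[p, p]
            phi[i, p] = phi[p, i] = phi[p, p]  # provisional; overridden below
            continue
        sire, dam = parent_of.get(ind, (None, None))
        si = idx.get(sire) if sire is not None else None
        di = idx.get(dam) if dam is not None else None
        for other in order[: order.index(ind)]:
            j = idx[other]
            contrib = 0.0
            contrib += phi[si, j] if si is not None else 0.0
            contrib += phi[di, j] if di is not None else 0.0
            denom = 2.0
            phi[i, j] = phi[j, i] = contrib / denom
        if si is not None and di is not None:
            phi[i, i] = 0.5 * (1 + phi[si, di])
        else:
            phi[i, i] = 0.5

    K = 2.0 * phi
    for sport, src in sport_of.items():
        i, j = idx[sport], idx[src]
        K[i, j] = K[j, i] = sport_value
    return KinshipMatrix(samples=order, values=K, source="pedigree")


def kinship_correlation(
    k_snp: KinshipMatrix,
    k_ped: KinshipMatrix,
    pairs: Sequence,
) -> tuple:
    """Pearson correlation of the two kinship estimates over listed pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    x = np.array([k_snp.get(a, b) for a, b in pairs])
    y = np.array([k_ped.get(a, b) for a, b in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant kinship values: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Inbreeding
# ---------------------------------------------------------------------------

def inbreeding_f(genotypes: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments inbreeding coefficient per sample.

    F = (O_hom - E_hom) / (m - E_hom), with E_hom = sum_k (1 - 2 p_k q_k)
    over the sample's non-missing calls at panel-polymorphic sites.
    Samples with no usable calls get NaN.
    """
    X = genotypes.dosages
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    het_exp = 2 * p * (1 - p)
    out = np.full(genotypes.n_samples, np.nan)
    for i in range(genotypes.n_samples):
        usable = poly & ~np.isnan(X[i])
        m = int(usable.sum())
        if m == 0:
            continue
        o_hom = float(np.sum((X[i, usable] == 0) | (X[i, usable] == 2)))
        e_hom = float(np.sum(1 - het_exp[usable]))
        denom = m - e_hom
        out[i] = (o_hom - e_hom) / denom if denom != 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# Network clustering
# ---------------------------------------------------------------------------

@dataclass
class KinCluster:
    cluster_id: str
    members: list
    degrees: dict
    mean_connectivity: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class NetworkResult:
    clusters: list  # KinCluster, ordered by size (Clr1 largest)
    small_groups: list  # components below min_cluster but with >= 1 edge
    isolated: list  # samples with no edge above threshold

    @property
    def clustered_total(self) -> int:
        return sum(c.size for c in self.clusters)


def kinship_network(
    kinship: KinshipMatrix,
    threshold: float = 0.45,
    min_cluster: int = 3,
) -> NetworkResult:
    """Threshold-graph clustering of a kinship matrix.

    Edges connect pairs with relatedness strictly above ``threshold``;
    connected components of size >= ``min_cluster`` become clusters,
    labelled Clr1, Clr2, ... in decreasing size (ties broken by first
    member id for determinism).  Smaller components are reported as
    isolated pairs / small groups; untouched samples as isolated.
    """
    g = nx.Graph()
    samples = kinship.samples
    g.add_nodes_from(samples)
    n = len(samples)
    for i in range(n):
        for j in range(i + 1, n):
            if kinship.values[i, j] > threshold:
                g.add_edge(samples[i], samples[j])

    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    big = [c for c in comps if len(c) >= min_cluster and len(c) >= 2]
    small = [c for c in comps if 2 <= len(c) < min_cluster]
    iso = [c[0] for c in comps if len(c) == 1]
    big.sort(key=lambda c: (-len(c), str(c[0])))

    clusters = []
    for k, members in enumerate(big, start=1):
        degrees = {m: g.degree(m) for m in members}
        clusters.append(
            KinCluster(
                cluster_id=f"Clr{k}",
                members=members,
                degrees=degrees,
                mean_connectivity=float(np.mean(list(degrees.values()))),
            )
        )
    return NetworkResult(clusters=clusters, small_groups=small, isolated=sorted(iso, key=str))


def cluster_share(clusters: Sequence[KinCluster]) -> dict:
    """Per-cluster share of the clustered total, rendered to 2 decimals."""
    total = sum(c.size for c in clusters)
    if total == 0:
        return {}
    return {c.cluster_id: render_percent(c.size, total) for c in clusters}
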