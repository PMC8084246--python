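"""Synthetic fixture generator with the structure the learner assumes.

A planted low-rank model: latent factors U (cell lines) and V (drugs)
drawn from seeded Gaussians produce continuous scores U V^T.  Each
drug's per-drug median acts as the C_max-style cutoff, so an IC50-like
matrix and a C_max table exist by construction and binarizing one
against the other reproduces the noiseless labels exactly.  Similarity
matrices mix the cosine similarity of the planted factors with
symmetric noise; chemical-protein and protein-protein networks plus a
drug-target map are sampled so every similarity constructor has valid
input.  Defaults are a desk-scale screen: 60 cell lines x 30 drugs,
rank 4, 5% label noise, 20% missing entries, 90% similarity fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    BinaryResponseMatrix,
    CmaxTable,
    DrugTargetMap,
    FeatureMatrix,
    ResponseMatrix,
    SimilarityMatrix,
    WeightedNetwork,
)


@dataclass
class SyntheticSpec:
    """Generator settings (defaults are the package's study conditions)."""

    m: int = 60
    n: int = 30
    k_true: int = 4
    noise: float = 0.05
    missing_frac: float = 0.2
    sim_fidelity: float = 0.9
    seed: int = 0
    n_expression_features: int = 50
    n_fingerprint_bits: int = 64
    n_proteins: int = 40

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2 or self.k_true < 1:
            raise ValueError("need m, n >= 2 and k_true >= 1")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must lie in [0, 1)")
        if not 0 <= self.sim_fidelity <= 1:
            raise ValueError("sim_fidelity must lie in [0, 1]")


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the ground truth."""

    binary_response: BinaryResponseMatrix
    response: ResponseMatrix
    cmax: CmaxTable
    expression: FeatureMatrix
    cnv: FeatureMatrix
    mutation: FeatureMatrix
    fingerprint: FeatureMatrix
    sc_raw: SimilarityMatrix
    sd_raw: SimilarityMatrix
    chem_protein_net: WeightedNetwork
    ppi_net: WeightedNetwork
    target_map: DrugTargetMap
    truth: dict = field(default_factory=dict)


def _cosine_similarity(F: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(F, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    S = (F / norms[:, None]) @ (F / norms[:, None]).T
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def _mixed_similarity(F: np.ndarray, fidelity: float,
                      rng: np.random.Generator) -> np.ndarray:
    S = _cosine_similarity(F)
    R = rng.uniform(-1.0, 1.0, size=S.shape)
    noise = 0.5 * (R + R.T)
    mixed = fidelity * S + (1.0 - fidelity) * noise
    np.clip(mixed, -1.0, 1.0, out=mixed)
    mixed = 0.5 * (mixed + mixed.T)
    np.fill_diagonal(mixed, 1.0)
    return mixed


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Draw one fully consistent synthetic screen."""
    rng = np.random.default_rng(spec.seed)
    m, n, k = spec.m, spec.n, spec.k_true
    cells = [f"CL{i:03d}" for i in range(m)]
    drugs = [f"DR{j:03d}" for j in range(n)]
    proteins = [f"PR{p:03d}" for p in range(spec.n_proteins)]

    U = rng.standard_normal((m, k))
    V = rng.standard_normal((n, k))
    scores = U @ V.T

    # per-drug median split: sensitive where the latent score beats the
    # drug's median, so a C_max-style cutoff exists by construction
    medians = np.median(scores, axis=0)
    B_clean = (scores > medians[None, :]).astype(float)

    flips = rng.random((m, n)) < spec.noise
    B_noisy = np.where(flips, 1.0 - B_clean, B_clean)

    # IC50-like values: low value = sensitive; C_max positive by design
    offsets = medians + rng.uniform(1.0, 3.0, size=n)
    ic50 = -scores + offsets[None, :]
    cmax = CmaxTable({d: float(offsets[j] - medians[j]) for j, d in enumerate(drugs)})

    missing = rng.random((m, n)) < spec.missing_frac
    binary_response = BinaryResponseMatrix(B_noisy, cells, drugs, missing.copy())
    response = ResponseMatrix(ic50, cells, drugs, missing.copy())

    # cell-line feature matrices driven by the latent factors
    p = spec.n_expression_features
    G = rng.standard_normal((k, p))
    expr = U @ G + 0.1 * rng.standard_normal((m, p))
    expression = FeatureMatrix(expr, cells, [f"G{g:03d}" for g in range(p)],
                               kind="expression")
    cnv_vals = U @ rng.standard_normal((k, p)) + 0.3 * rng.standard_normal((m, p))
    cnv_missing = rng.random((m, p)) < min(0.05, spec.missing_frac)
    cnv = FeatureMatrix(cnv_vals, cells, [f"G{g:03d}" for g in range(p)],
                        kind="cnv", missing_mask=cnv_missing)
    mut_prob = 1.0 / (1.0 + np.exp(-(U @ rng.standard_normal((k, p)))))
    mutation = FeatureMatrix((rng.random((m, p)) < mut_prob).astype(float),
                             cells, [f"G{g:03d}" for g in range(p)], kind="mutation")

    # drug fingerprints driven by V
    q = spec.n_fingerprint_bits
    fp_prob = 1.0 / (1.0 + np.exp(-(V @ rng.standard_normal((k, q)))))
    fingerprint = FeatureMatrix((rng.random((n, q)) < fp_prob).astype(float),
                                drugs, [f"BIT{b:03d}" for b in range(q)],
                                kind="fingerprint")

    sc_raw = SimilarityMatrix(_mixed_similarity(U, spec.sim_fidelity, rng),
                              cells, "cell_line", "SC_E", "raw")
    sd_raw = SimilarityMatrix(_mixed_similarity(V, spec.sim_fidelity, rng),
                              drugs, "drug", "SD_S", "raw")

    # protein latent positions; drugs target nearby proteins so the
    # network similarities correlate with the planted factors
    P = rng.standard_normal((spec.n_proteins, k))
    affinity = V @ P.T  # n x proteins
    chem_protein = WeightedNetwork()
    target_map = DrugTargetMap({})
    for j, d in enumerate(drugs):
        top = np.argsort(-affinity[j])[:4]
        target_map.targets[d] = {proteins[t] for t in top[:1 + int(rng.integers(1, 4))]}
        for t in top:
            chem_protein.add_edge(d, proteins[t],
                                  float(1.0 + np.abs(affinity[j, t])))
    ppi = WeightedNetwork()
    prot_sim = _cosine_similarity(P)
    for a in range(spec.n_proteins):
        for b in range(a + 1, spec.n_proteins):
            if prot_sim[a, b] > 0.5 or rng.random() < 0.05:
                ppi.add_edge(proteins[a], proteins[b],
                             float(np.clip(0.5 + 0.5 * prot_sim[a, b], 0.1, 1.0)))

    truth = {"U": U, "V": V, "B_clean": B_clean, "scores": scores}
    return SyntheticBundle(
        binary_response=binary_response, response=response, cmax=cmax,
        expression=expression, cnv=cnv, mutation=mutation,
        fingerprint=fingerprint, sc_raw=sc_raw, sd_raw=sd_raw,
        chem_protein_net=chem_protein, ppi_net=ppi, target_map=target_map,
        truth=truth,
    )
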