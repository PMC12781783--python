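"""Synthetic bundles with known ground truth.

Emulates the structure the completion model assumes: expression profiles
driven by a small number of latent factors, responses lying (approximately)
in the span of the expression principal components, per-drug missingness,
and binary mutations that shift response distributions by a configurable
effect size in the sensitive direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .data import (ExpressionMatrix, MutationProfile, Orientation,
                   ResponseMatrix, TissueMap, write_matrix, write_tissue_map)
from .pca import fit_pca


@dataclass
class GeneratorSpec:
    """Configuration of the synthetic bundle.

    Responses are planted directly on the normalized scale (mean-0, sd-1
    columns before effects and noise). ``span_leak`` is the fraction of
    response variance placed orthogonal to the expression score span;
    mutation effects shift carrier cell lines' responses by ``shift`` column
    standard deviations in the sensitive direction (location shifts only).
    """

    m: int = 80
    n: int = 200
    p: int = 12
    k_true: int = 4
    noise_sd: float = 0.1
    missing_fraction: float = 0.3
    span_leak: float = 0.0
    mutation_effects: list[tuple[int, int, float]] = field(default_factory=list)
    co_mutation_effects: list[tuple[int, int, int, float]] = field(default_factory=list)
    mutation_prevalence: float = 0.3
    tissue_count: int = 5
    orientation: Orientation = "higher_is_sensitive"
    expression_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_true <= min(self.m - 1, self.p):
            raise ValueError("k_true must be <= min(m-1, p)")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not 0 <= self.span_leak <= 1:
            raise ValueError("span_leak must be in [0, 1]")
        if not 0 < self.mutation_prevalence < 1:
            raise ValueError("mutation_prevalence must be in (0, 1)")


@dataclass
class SyntheticBundle:
    expression: ExpressionMatrix
    response: ResponseMatrix  # raw view: NaN at masked entries
    mutations: MutationProfile
    tissues: TissueMap
    M_true: np.ndarray        # noiseless, effect-free complete matrix
    response_complete: np.ndarray  # with effects and noise, before masking
    Lambda_star: np.ndarray
    effect_table: list[dict]
    spec: GeneratorSpec


def _standardize_cols(A: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return A / sd


def generate(spec: GeneratorSpec) -> SyntheticBundle:
    """Draw one fully specified bundle, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    m, n, p, k = spec.m, spec.n, spec.p, spec.k_true

    # expression: k_true latent factors plus isotropic noise
    Z = rng.standard_normal((m, k))
    B = rng.standard_normal((n, k))
    X = Z @ B.T + spec.expression_noise_sd * rng.standard_normal((m, n))
    cell_ids = [f"CL{i:04d}" for i in range(m)]
    gene_ids = [f"G{j:05d}" for j in range(n)]
    drug_ids = [f"D{j:03d}" for j in range(p)]
    expression = ExpressionMatrix(X, cell_ids, gene_ids)

    # responses in the span of the realized expression scores
    U = fit_pca(expression, n_components=k).scores
    Lambda_star = rng.standard_normal((k, p))
    M_in = _standardize_cols(U @ Lambda_star)
    if spec.span_leak > 0:
        E = rng.standard_normal((m, p))
        E -= U @ np.linalg.lstsq(U, E, rcond=None)[0]
        E = _standardize_cols(E)
        M_true = (np.sqrt(1 - spec.span_leak) * M_in
                  + np.sqrt(spec.span_leak) * E)
    else:
        M_true = M_in

    mutations = MutationProfile(
        (rng.random((m, n)) < spec.mutation_prevalence).astype(np.int8),
        cell_ids, gene_ids)

    sign = 1.0 if spec.orientation == "higher_is_sensitive" else -1.0
    response = M_true.copy()
    col_sd = M_true.std(axis=0, ddof=1)
    effect_table: list[dict] = []
    for gene, drug, shift in spec.mutation_effects:
        if not (0 <= gene < n and 0 <= drug < p):
            raise ValueError(f"effect references unknown gene/drug ({gene}, {drug})")
        carriers = mutations.calls[:, gene] == 1
        response[carriers, drug] += sign * shift * col_sd[drug]
        effect_table.append({"kind": "single", "gene": gene_ids[gene],
                             "drug": drug_ids[drug], "shift_sd": shift,
                             "n_carriers": int(carriers.sum())})
    for ga, gb, drug, shift in spec.co_mutation_effects:
        if not (0 <= ga < n and 0 <= gb < n and 0 <= drug < p):
            raise ValueError(
                f"co-mutation effect references unknown indices ({ga}, {gb}, {drug})")
        both = (mutations.calls[:, ga] == 1) & (mutations.calls[:, gb] == 1)
        response[both, drug] += sign * shift * col_sd[drug]
        effect_table.append({"kind": "co", "gene_a": gene_ids[ga],
                             "gene_b": gene_ids[gb], "drug": drug_ids[drug],
                             "shift_sd": shift, "n_carriers": int(both.sum())})

    response_complete = response + spec.noise_sd * rng.standard_normal((m, p))

    mask = np.ones((m, p), dtype=bool)
    n_hide = int(np.floor(spec.missing_fraction * m))
    for j in range(p):
        if n_hide > 0:
            mask[rng.choice(m, size=n_hide, replace=False), j] = False
    raw = response_complete.copy()
    raw[~mask] = np.nan
    response_rm = ResponseMatrix(raw, mask, cell_ids, drug_ids,
                                 spec.orientation)

    tissue_labels = rng.integers(spec.tissue_count, size=m)
    tissues = TissueMap({cid: f"tissue_{t}" for cid, t
                         in zip(cell_ids, tissue_labels)})

    return SyntheticBundle(expression, response_rm, mutations, tissues,
                           M_true, response_complete, Lambda_star,
                           effect_table, spec)


def null_bundle(spec: GeneratorSpec) -> SyntheticBundle:
    """The calibration null: same bundle with all mutation effects removed."""
    return generate(replace(spec, mutation_effects=[], co_mutation_effects=[]))


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the four data files plus ground truth in read_matrix dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "response": out / "response.tsv",
        "expression": out / "expression.tsv",
        "mutations": out / "mutations.tsv",
        "tissues": out / "tissues.tsv",
        "M_true": out / "ground_truth_M_true.tsv",
        "Lambda_star": out / "ground_truth_Lambda.tsv",
    }
    write_matrix(bundle.response, paths["response"])
    write_matrix(bundle.expression, paths["expression"])
    write_matrix(bundle.mutations, paths["mutations"])
    write_tissue_map(bundle.tissues, paths["tissues"])
    np.savetxt(paths["M_true"], bundle.M_true, delimiter="\t")
    np.savetxt(paths["Lambda_star"], bundle.Lambda_star, delimiter="\t")
    return paths
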