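"""Synthetic expression data with planted co-expression modules.

Each planted module shares one latent per-sample profile; a member gene is
latent + independent Gaussian noise, so the expected correlation between
two members of the same module is var(latent) / (var(latent) + sigma^2)
= 1 / (1 + sigma^2) for a unit-variance latent.  Background genes are
independent noise and are uncorrelated with everything in expectation.
Missing entries are masked uniformly at random.  Matching annotation
categories mirror the planted modules, optionally corrupted by swapping a
fraction of each category's genes with background genes, which lets tests
exercise imperfect annotation matches.

The generator is the study bench for the whole toolkit: module sizes are
chosen to populate all three evaluation size bins, and the default sample
count (52) matches a typical stress-response microarray compendium.  All
output is a pure function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationCollection, Clustering, ExpressionMatrix, InvalidInputError

__all__ = ["SyntheticSpec", "generate", "small_worked_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``within_module_corr`` sets the target expected |r| between genes of
    the same module; the implied noise standard deviation is
    sqrt((1 - r) / r) for the unit-variance latent, unless ``noise_sd``
    is given explicitly.
    """

    n_genes: int = 250
    n_samples: int = 52
    module_sizes: tuple[int, ...] = (8, 40, 120)
    within_module_corr: float = 0.9
    noise_sd: float | None = None
    missing_rate: float = 0.02
    annotation_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise InvalidInputError("module sizes exceed the gene count")
        if not (0.0 < self.within_module_corr < 1.0) and self.noise_sd is None:
            raise InvalidInputError("within_module_corr must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidInputError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.annotation_noise <= 1.0):
            raise InvalidInputError("annotation_noise must lie in [0, 1]")
        if self.n_samples < 2:
            raise InvalidInputError("at least 2 samples are required")
        if any(m < 1 for m in self.module_sizes):
            raise InvalidInputError("module sizes must be positive")

    @property
    def sigma(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        r = self.within_module_corr
        return float(np.sqrt((1.0 - r) / r))


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, AnnotationCollection, Clustering]:
    """Draw one dataset: expression, annotations, and the planted truth."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    values = np.empty((spec.n_genes, spec.n_samples))
    sigma = spec.sigma

    modules: list[list[str]] = []
    row = 0
    for size in spec.module_sizes:
        latent = rng.standard_normal(spec.n_samples)
        noise = rng.standard_normal((size, spec.n_samples)) * sigma
        values[row : row + size] = latent[None, :] + noise
        modules.append(gene_ids[row : row + size])
        row += size
    n_background = spec.n_genes - row
    if n_background:
        values[row:] = rng.standard_normal((n_background, spec.n_samples))
    background = gene_ids[row:]

    mask = rng.random((spec.n_genes, spec.n_samples)) < spec.missing_rate
    # never mask a full gene: correlations need data on every row
    full = mask.all(axis=1)
    mask[full, 0] = False
    expr = ExpressionMatrix(gene_ids=gene_ids, values=values, missing_mask=mask)

    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for k, members in enumerate(modules, start=1):
        cat = set(members)
        n_swap = int(round(spec.annotation_noise * len(members)))
        n_swap = min(n_swap, len(members) - 1, len(background))
        if n_swap > 0:
            out = rng.choice(sorted(cat), size=n_swap, replace=False)
            into = rng.choice(background, size=n_swap, replace=False)
            cat -= set(out)
            cat |= set(into)
        cid = f"M{k}"
        categories[cid] = frozenset(cat)
        descriptions[cid] = f"planted module {k} ({len(members)} genes)"
    ann = AnnotationCollection(
        source="planted", categories=categories, descriptions=descriptions
    )
    truth = Clustering(
        method="ground_truth",
        parameters={"seed": spec.seed},
        clusters=[frozenset(m) for m in modules],
        ids=[f"M{k}" for k in range(1, len(modules) + 1)],
    )
    return expr, ann, truth


#: frozen spec of the small worked example used in docs and golden tests
FIXTURE_SPEC = SyntheticSpec(
    n_genes=60,
    n_samples=12,
    module_sizes=(5, 15, 30),
    within_module_corr=0.95,  # 12 samples are few; a tight fixture keeps golden outputs stable
    missing_rate=0.0,
    annotation_noise=0.0,
    seed=20120625,
)


def small_worked_fixture() -> tuple[ExpressionMatrix, AnnotationCollection, Clustering]:
    """The bundled tiny dataset: 60 genes x 12 samples, modules of 5/15/30.

    Regenerated deterministically from a frozen spec, so repeated calls
    are byte-identical; golden tests and the README worked example rely on
    its recovered structure.
    """
    return generate(FIXTURE_SPEC)
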