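"""Deterministic synthetic inputs: worked examples and planted-structure data.

Two families of fixtures:

* hand-built worked examples — the square-with-both-diagonals
  filtration whose persistence pairing is known stage by stage, and the
  six-gene annotation instance whose exact minimum cover size is 3;

* seeded generators — labelled point clouds with planted geometric
  structure per class (circle / sphere / torus / blob) plus a fraction
  of "outlier" cohorts whose rows are replaced by broad uniform noise
  while *keeping* their class label, emulating instrument or curation
  errors that dominant-cycle curation should remove; and annotation
  maps with planted gene families sharing a family term.

Every generator is a pure function of its configuration (identical
seeds give byte-identical output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_curation import ExpressionDataset
from .complex_core import Filtration
from .gene_curation import NOT_ANNOTATED, AnnotationMap

__all__ = [
    "square_diagonals_filtration",
    "six_gene_annotations",
    "PlantedCohortConfig",
    "planted_cohorts",
    "planted_annotations",
    "noisy_circle",
    "noisy_sphere",
]


def square_diagonals_filtration() -> Filtration:
    """The worked square-with-both-diagonals filtration.

    Vertices a,b,c,d (0..3) enter at stage 0; the spanning-tree edges
    ab, bc, cd at stages 1..3; the closing edge da at stage 4; the
    diagonals ac at 5 and bd at 6; triangles abd, abc, acd at stages
    7, 8, 9.  Stages are encoded as filtration *values*, so the three
    H1 classes are born at values 4, 5, 6 and die at 9, 8, 7: pairing
    yields the intervals (6,7), (5,8) and (4,9) on the value scale.
    """
    a, b, c, d = 0, 1, 2, 3
    entries = [
        ((a,), 0.0), ((b,), 0.0), ((c,), 0.0), ((d,), 0.0),
        ((a, b), 1.0),
        ((b, c), 2.0),
        ((c, d), 3.0),
        ((a, d), 4.0),   # da: creator of the big hole, dies at 9
        ((a, c), 5.0),   # diagonal ac, dies at 8
        ((b, d), 6.0),   # diagonal bd, dies at 7
        ((a, b, d), 7.0),
        ((a, b, c), 8.0),
        ((a, c, d), 9.0),
    ]
    return Filtration([s for s, _ in entries], [v for _, v in entries])


def six_gene_annotations() -> tuple[list[int], AnnotationMap]:
    """Six genes with the printed annotation sets; exact cover size 3.

    Both capitalisation variants of the unannotated marker are
    normalised to the single reserved term.
    """
    terms = {
        1: {"Localization"},
        2: {NOT_ANNOTATED},
        3: {"Metabolic process", "Cellular process"},
        4: {"Metabolic process", "Cellular process", "Biological regulation"},
        5: {"Metabolic process", "Cellular process", "Localization"},
        6: {NOT_ANNOTATED},
    }
    return list(terms), AnnotationMap(terms)


@dataclass
class PlantedCohortConfig:
    """Configuration of the planted-structure cohort generator.

    Each class samples points from a geometric structure (embedded in
    the first coordinates of the m-dimensional ambient space) plus
    isotropic Gaussian noise; ``outlier_fraction`` of all cohorts are
    replaced by broad uniform rows while keeping their labels.
    """

    n_per_class: tuple[int, ...] = (40, 40)
    m: int = 6
    structures: tuple[dict, ...] = (
        {"kind": "sphere", "center": (0.0, 0.0, 0.0), "radius": 3.0},
        {"kind": "sphere", "center": (12.0, 0.0, 0.0), "radius": 3.0},
    )
    noise_sd: float = 0.15
    outlier_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class entries must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.structures) != len(self.n_per_class):
            raise ValueError("one structure per class required")


def _sample_structure(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-scale samples of the named structure, centred at the origin."""
    if kind == "sphere":
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    if kind == "circle":
        th = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([np.cos(th), np.sin(th)])
    if kind == "torus":
        th = rng.uniform(0, 2 * np.pi, size=n)
        ph = rng.uniform(0, 2 * np.pi, size=n)
        r_minor = 0.4
        return np.column_stack(
            [
                (1 + r_minor * np.cos(ph)) * np.cos(th),
                (1 + r_minor * np.cos(ph)) * np.sin(th),
                r_minor * np.sin(ph),
            ]
        )
    if kind == "gaussian_blob":
        return rng.normal(size=(n, 3))
    raise ValueError(f"unknown structure kind {kind!r}")


def planted_cohorts(
    cfg: PlantedCohortConfig | None = None,
) -> tuple[ExpressionDataset, dict]:
    """Generate a labelled cohort matrix with planted class geometry.

    Returns the dataset and a ground-truth map cohort_id -> True for
    inliers / False for the uniformly-scrambled outlier cohorts.
    """
    cfg = cfg or PlantedCohortConfig()
    rng = np.random.default_rng(cfg.seed)
    rows, labels = [], []
    for cls, (n, st) in enumerate(zip(cfg.n_per_class, cfg.structures)):
        base = _sample_structure(st["kind"], n, rng) * st.get("radius", 1.0)
        center = np.asarray(st.get("center", (0.0,) * base.shape[1]), dtype=float)
        if base.shape[1] > cfg.m:
            raise ValueError("structure dimension exceeds ambient dimension m")
        emb = np.zeros((n, cfg.m))
        emb[:, : base.shape[1]] = base + center
        emb += rng.normal(scale=cfg.noise_sd, size=emb.shape)
        rows.append(emb)
        labels.extend([cls] * n)
    values = np.vstack(rows)
    n_total = values.shape[0]
    n_out = int(round(cfg.outlier_fraction * n_total))
    out_idx = rng.choice(n_total, size=n_out, replace=False)
    lo, hi = values.min() - 1.0, values.max() + 1.0
    values[out_idx] = rng.uniform(lo, hi, size=(n_out, cfg.m))
    cohort_ids = [f"c{i:03d}" for i in range(n_total)]
    gene_ids = [f"g{j:03d}" for j in range(cfg.m)]
    ds = ExpressionDataset(
        values, cohort_ids, gene_ids, dict(zip(cohort_ids, labels))
    )
    truth = {c: True for c in cohort_ids}
    for i in out_idx:
        truth[cohort_ids[i]] = False
    return ds, truth


def planted_annotations(
    gene_ids,
    n_families: int = 3,
    family_size: int = 5,
    vocab: tuple[str, ...] = (),
    extra_term_prob: float = 0.3,
    seed: int = 0,
) -> tuple[AnnotationMap, dict]:
    """Annotation map with planted gene families.

    The first ``n_families * family_size`` genes are partitioned into
    families; each family's genes share the term ``family<i>`` plus,
    with probability ``extra_term_prob``, one extra term drawn from
    ``vocab``.  Leftover genes are "Not annotated".  Also returns the
    ground-truth map gene -> family index (or None).
    """
    gene_ids = list(gene_ids)
    if n_families * family_size > len(gene_ids):
        raise ValueError("families do not fit within the gene count")
    rng = np.random.default_rng(seed)
    terms: dict = {}
    family_of: dict = {}
    for i in range(n_families):
        fam_term = f"family{i}"
        for g in gene_ids[i * family_size : (i + 1) * family_size]:
            ts = {fam_term}
            if vocab and rng.random() < extra_term_prob:
                ts.add(str(rng.choice(list(vocab))))
            terms[g] = ts
            family_of[g] = i
    for g in gene_ids[n_families * family_size :]:
        terms[g] = {NOT_ANNOTATED}
        family_of[g] = None
    return AnnotationMap(terms), family_of


def noisy_circle(n: int = 30, noise_sd: float = 0.05, seed: int = 0) -> np.ndarray:
    """n seeded points near the unit circle in the plane."""
    rng = np.random.default_rng(seed)
    th = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    pts = np.column_stack([np.cos(th), np.sin(th)])
    return pts + rng.normal(scale=noise_sd, size=pts.shape)


def noisy_sphere(n: int = 40, noise_sd: float = 0.05, seed: int = 0) -> np.ndarray:
    """n seeded points near the unit 2-sphere in 3-space."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    pts = v / np.linalg.norm(v, axis=1, keepdims=True)
    return pts + rng.normal(scale=noise_sd, size=pts.shape)
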