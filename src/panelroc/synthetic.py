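"""Synthetic two-class marker tables and gene-by-cell expression fixtures.

These generators let every stage of the pipeline be exercised and validated
without any external download.  Signals are log-normal — non-negative and
right-skewed, like assay intensities — and a chosen subset of *planted*
markers carries the class signal.

Two planted-effect geometries are supported:

``uniform``
    Every case sample's planted markers are shifted up by ``effect``.  Each
    planted marker is then individually discriminative, and (with
    combithr=1) single markers tend to dominate combinations by Youden
    index: unions add little sensitivity but multiply away specificity.

``complementary``
    Each case sample elevates exactly one planted marker (assigned
    round-robin).  No single marker covers all cases, so the full planted
    set is the genuinely optimal combination — the complementary-marker
    regime a combinatorial panel search exists for.

The expression fixture emulates the classic annotation-transfer difficulty:
a *target* cluster elevates the whole signature, while a *confounder*
cluster elevates a designated overlapping subset of it, so single
overlapping genes cannot separate target from rest but a combination of the
non-overlapping genes can.  Dropout is injected as independent zeroing.

All randomness flows through one seeded ``numpy.random.Generator``; the same
seed reproduces byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import SpecError
from .tables import MarkerTable

CASE_LABEL = "case"
CONTROL_LABEL = "control"


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


@dataclass
class SyntheticSpec:
    """Study conditions for a two-class marker table.

    Defaults describe a moderately noisy assay: baseline signal around 100
    units with sd 25, ten markers of which three are planted with a location
    shift of 100 (= 4 x noise sd) in the case class, 100 samples per class.
    """

    n_case: int = 100
    n_control: int = 100
    n_markers: int = 10
    planted_members: tuple[str, ...] = ("M01", "M02", "M03")
    effect: float = 100.0
    noise_sd: float = 25.0
    baseline_mean: float = 100.0
    effect_mode: Literal["uniform", "complementary"] = "uniform"
    seed: int = 0

    def marker_names(self) -> list[str]:
        width = max(2, len(str(self.n_markers)))
        return [f"M{i + 1:0{width}d}" for i in range(self.n_markers)]

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise SpecError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        if self.n_case < 1 or self.n_control < 1:
            raise SpecError("need at least one sample per class")
        names = set(self.marker_names())
        bad = [m for m in self.planted_members if m not in names]
        if bad:
            raise SpecError(
                f"planted member(s) not among generated markers: {', '.join(bad)}"
            )


def generate_two_class_table(spec: SyntheticSpec) -> tuple[MarkerTable, dict]:
    """Generate a labeled two-class marker table plus its ground truth.

    Non-planted markers are drawn identically for both classes (log-normal
    with mean ``baseline_mean`` and sd ``noise_sd``); planted markers gain a
    location shift of ``effect`` in the case class (every case sample in
    ``uniform`` mode; one planted marker per case sample, round-robin, in
    ``complementary`` mode).  Signals are truncated at 0.
    """
    rng = np.random.default_rng(spec.seed)
    markers = spec.marker_names()
    n = spec.n_case + spec.n_control
    mu, sigma = _lognormal_params(spec.baseline_mean, spec.noise_sd)
    base = rng.lognormal(mean=mu, sigma=sigma, size=(n, spec.n_markers))

    planted_idx = [markers.index(m) for m in spec.planted_members]
    if planted_idx and spec.effect > 0:
        if spec.effect_mode == "uniform":
            base[: spec.n_case, planted_idx] += spec.effect
        else:
            assigned = np.arange(spec.n_case) % len(planted_idx)
            for j, col in enumerate(planted_idx):
                base[np.nonzero(assigned == j)[0], col] += spec.effect

    signals = pd.DataFrame(
        np.clip(base, 0.0, None),
        index=pd.Index(
            [f"S{i + 1:04d}" for i in range(n)], name="ID"
        ),
        columns=markers,
    )
    classes = pd.Series(
        [CASE_LABEL] * spec.n_case + [CONTROL_LABEL] * spec.n_control,
        index=signals.index,
    )
    table = MarkerTable(
        signals=signals,
        classes=classes,
        case_label=CASE_LABEL,
        control_label=CONTROL_LABEL,
    )
    truth = {
        "planted_members": list(spec.planted_members),
        "effect": spec.effect,
        "effect_mode": spec.effect_mode,
        "noise_sd": spec.noise_sd,
        "baseline_mean": spec.baseline_mean,
        "seed": spec.seed,
    }
    return table, truth


def generate_expression_fixture(
    n_genes: int = 40,
    cluster_sizes: dict[str, int] | None = None,
    signature_genes: Sequence[str] | None = None,
    overlap_genes: Sequence[str] | None = None,
    target_cluster: str = "target",
    confounder_cluster: str = "confounder",
    base_mean: float = 1.0,
    elevated_mean: float = 6.0,
    noise_sd: float = 1.0,
    dropout_rate: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate a gene-by-cell matrix with a target/confounder overlap design.

    The target cluster elevates *all* signature genes; the confounder cluster
    elevates only ``overlap_genes`` (a subset of the signature).  Expression
    is ``clip(mean + N(0, noise_sd), 0)`` with independent dropout zeroing at
    ``dropout_rate`` — so with zero noise and zero dropout, cluster means
    equal the configured means exactly.

    Returns (matrix, per-cell annotations indexed by barcode, truth dict).
    """
    if cluster_sizes is None:
        cluster_sizes = {"target": 150, "confounder": 300, "other": 150}
    if signature_genes is None:
        signature_genes = [f"SIG{i + 1:02d}" for i in range(12)]
    if overlap_genes is None:
        overlap_genes = list(signature_genes[:3])
    signature_genes = list(signature_genes)
    overlap_genes = list(overlap_genes)
    if len(signature_genes) > n_genes:
        raise SpecError("signature genes exceed n_genes")
    if not set(overlap_genes) <= set(signature_genes):
        raise SpecError("overlap genes must be a subset of the signature")
    for cl in (target_cluster, confounder_cluster):
        if cl not in cluster_sizes:
            raise SpecError(f"cluster {cl!r} missing from cluster_sizes")

    rng = np.random.default_rng(seed)
    filler = [f"G{i + 1:03d}" for i in range(n_genes - len(signature_genes))]
    genes = signature_genes + filler
    labels = np.concatenate(
        [np.full(size, name, dtype=object) for name, size in cluster_sizes.items()]
    )
    n_cells = labels.size
    barcodes = [f"CELL{i + 1:05d}" for i in range(n_cells)]

    means = np.full((len(genes), n_cells), base_mean, dtype=float)
    gene_idx = {g: i for i, g in enumerate(genes)}
    in_target = labels == target_cluster
    in_confounder = labels == confounder_cluster
    for g in signature_genes:
        means[gene_idx[g], in_target] = elevated_mean
    for g in overlap_genes:
        means[gene_idx[g], in_confounder] = elevated_mean

    values = means.copy()
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    if dropout_rate > 0:
        values[rng.random(values.shape) < dropout_rate] = 0.0

    matrix = pd.DataFrame(values, index=genes, columns=barcodes)
    annotations = pd.Series(labels, index=barcodes)
    truth = {
        "signature_genes": signature_genes,
        "overlap_genes": overlap_genes,
        "target_cluster": target_cluster,
        "confounder_cluster": confounder_cluster,
        "cluster_sizes": dict(cluster_sizes),
        "base_mean": base_mean,
        "elevated_mean": elevated_mean,
        "noise_sd": noise_sd,
        "dropout_rate": dropout_rate,
        "seed": seed,
    }
    return matrix, annotations, truth
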