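"""Split spot expression into pure-cell-type sub-spots.

A barcoded spot covers several cells of possibly different types, so its gene
counts are a mixture. With the imaging side supplying the per-spot cell-type
proportions beta[i, k] and a single-cell reference supplying per-type mean
expression mu[k, j], each spot's count for gene j is apportioned among the
types present in it:

    xhat[i, j, k] = x[i, j] * beta[i, k] * mu[k, j] / sum_k' beta[i, k'] * mu[k', j]

Each (spot, type) pair with beta > 0 becomes a "sub-spot": a pure-cell-type
pseudo-observation carrying the split expression, and — from the imaging side
— the mean scaled protein profile of that spot's cells of that type. The
paired sub-spot matrices are the inputs to downstream multimodal integration
(e.g. a weighted-nearest-neighbour analysis); that integration itself is out
of scope here.

The split conserves counts by construction: summing xhat over types recovers
x wherever the denominator is positive, and also under the beta fallback used
when a gene's denominator vanishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .grid import SpotComposition
from .preprocess import ProteinMatrix

__all__ = [
    "ReferenceProfile",
    "compute_reference_profiles",
    "SubSpotMatrix",
    "split_spots",
    "aggregate_protein_subspots",
    "LabelClassifier",
    "train_label_classifier",
    "predict_labels",
    "export_wnn_inputs",
]

logger = logging.getLogger(__name__)


@dataclass
class ReferenceProfile:
    """Type-by-gene mean expression from a single-cell reference.

    ``normalization`` records how cells were scaled before averaging so the
    provenance of mu is explicit in every output.
    """

    mu: pd.DataFrame  # types x genes
    normalization: str = "median-library-size"

    def __post_init__(self):
        if (self.mu.to_numpy() < 0).any():
            raise ValueError("reference profiles must be nonnegative")


def compute_reference_profiles(
    ref_counts: pd.DataFrame,
    ref_labels: pd.Series,
    norm: str = "median-library-size",
) -> ReferenceProfile:
    """Average reference cells into per-type profiles mu[k, j].

    With the default normalisation each cell is scaled to the median library
    size before averaging, so types with deeper-sequenced cells do not get
    inflated profiles; ``norm="raw"`` averages raw counts.
    """
    labels = ref_labels.reindex(ref_counts.index)
    if labels.isna().any():
        raise ValueError("every reference cell needs a type label")
    counts = ref_counts.to_numpy(dtype=float)
    if norm == "median-library-size":
        totals = counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("reference contains cells with zero total counts")
        target = float(np.median(totals))
        counts = counts * (target / totals)[:, None]
    elif norm != "raw":
        raise ValueError(f"unknown normalisation mode {norm!r}")
    df = pd.DataFrame(counts, index=ref_counts.index, columns=ref_counts.columns)
    mu = df.groupby(labels.to_numpy()).mean()
    if (mu.index.value_counts() == 0).any():  # pragma: no cover - groupby cannot emit empties
        raise ValueError("empty cell type in reference")
    mu.index.name = "type"
    return ReferenceProfile(mu=mu, normalization=norm)


@dataclass
class SubSpotMatrix:
    """Pure-cell-type sub-spots: split expression plus matched protein profiles.

    Rows are indexed by (spot, type) pairs with beta > 0. ``protein`` and
    ``meta`` may cover a subset of rows (spot/type combinations with no
    imaging cells have no protein aggregate). ``report`` records skipped
    spots, dropped genes and fallback usage for auditing.
    """

    x: pd.DataFrame  # MultiIndex (spot, type) x genes
    protein: Optional[pd.DataFrame] = None  # MultiIndex (spot, type) x markers
    meta: Optional[pd.DataFrame] = None  # per-sub-spot coordinates / n_cells
    report: dict = field(default_factory=dict)

    def conservation_error(self, x: pd.DataFrame) -> float:
        """Max relative error of sum_k xhat against x over the split spots."""
        totals = self.x.groupby(level="spot", sort=False).sum()
        ref = x.loc[totals.index, totals.columns]
        denom = np.maximum(ref.to_numpy(dtype=float), 1.0)
        return float(np.max(np.abs(totals.to_numpy() - ref.to_numpy()) / denom))


def split_spots(
    x: pd.DataFrame,
    beta: SpotComposition,
    mu: ReferenceProfile,
    fallback: str = "beta",
) -> SubSpotMatrix:
    """Apportion each spot's gene counts among its cell types.

    Applies ``xhat = x * beta * mu / (beta @ mu)`` gene-wise per spot.
    Sub-spots are emitted only for types with beta > 0. Genes absent from the
    reference are dropped (counted in the report). Spots in ``x`` whose
    composition is undefined (no imaging cells) are skipped, not zero-filled.
    For a gene whose denominator is 0 in some spot while x > 0, the count is
    distributed proportionally to beta (``fallback="beta"``, conserving mass)
    or zeroed (``fallback="drop"``); either way the affected genes are logged.
    """
    if fallback not in ("beta", "drop"):
        raise ValueError(f"fallback must be 'beta' or 'drop', got {fallback!r}")
    b = beta.beta
    present_types = [t for t in b.columns if (b[t] > 0).any()]
    missing = [t for t in present_types if t not in mu.mu.index]
    if missing:
        raise ValueError(f"cell type(s) present in the composition but absent from the reference: {missing}")

    genes = [g for g in x.columns if g in set(mu.mu.columns)]
    n_dropped_genes = x.shape[1] - len(genes)
    if n_dropped_genes:
        logger.info("dropping %d gene(s) absent from the reference", n_dropped_genes)

    spots = [s for s in x.index if s in b.index]
    skipped = [s for s in x.index if s not in b.index]
    if skipped:
        logger.info("skipping %d spot(s) with undefined composition", len(skipped))

    B = b.loc[spots, :].to_numpy(dtype=float)  # spots x K
    types = list(b.columns)
    M = mu.mu.reindex(index=types, columns=genes).fillna(0.0).to_numpy(dtype=float)  # K x G
    X = x.loc[spots, genes].to_numpy(dtype=float)
    D = B @ M  # spots x G

    zero_den = D <= 0
    fallback_cells = zero_den & (X > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(zero_den[:, None, :], 0.0, (B[:, :, None] * M[None, :, :]) / np.where(D == 0, 1.0, D)[:, None, :])
    xhat = X[:, None, :] * W  # spots x K x G
    if fallback == "beta":
        xhat += np.where(fallback_cells[:, None, :], X[:, None, :] * B[:, :, None], 0.0)
    n_fallback = int(fallback_cells.sum())
    if n_fallback:
        affected = sorted({genes[g] for g in np.nonzero(fallback_cells.any(axis=0))[0]})
        logger.info(
            "zero-denominator fallback (%s) applied to %d spot-gene entries across gene(s) %s",
            fallback,
            n_fallback,
            affected[:20],
        )

    rows = []
    index = []
    for si, s in enumerate(spots):
        for ki, t in enumerate(types):
            if B[si, ki] > 0:
                rows.append(xhat[si, ki])
                index.append((s, t))
    out = pd.DataFrame(
        np.asarray(rows) if rows else np.empty((0, len(genes))),
        index=pd.MultiIndex.from_tuples(index, names=["spot", "type"]) if index else
        pd.MultiIndex.from_arrays([[], []], names=["spot", "type"]),
        columns=genes,
    )
    report = {
        "n_spots_split": len(spots),
        "n_spots_skipped_undefined": len(skipped),
        "skipped_spots": skipped,
        "n_genes_dropped_no_reference": int(n_dropped_genes),
        "n_fallback_entries": n_fallback,
        "fallback_mode": fallback,
        "x_scale": "raw-counts-as-provided",
    }
    return SubSpotMatrix(x=out, report=report)


def aggregate_protein_subspots(
    cells: pd.DataFrame,
    protein: ProteinMatrix,
    assignment: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate imaging cells into per-(spot, type) mean protein profiles.

    Returns the (spot, type)-indexed mean scaled protein matrix and a matching
    metadata table with the sub-spot coordinate (centroid of member cells in
    the registered frame) and member count. Spot/type combinations with no
    cells are simply absent.
    """
    lab = cells.set_index("cell_id")["label"]
    pos = cells.set_index("cell_id")[["x", "y"]]
    mapped = assignment.dropna()
    if mapped.empty:
        raise ValueError("no cells are assigned to any spot")
    key = pd.DataFrame({"spot": mapped, "type": lab.reindex(mapped.index)})
    if key["type"].isna().any():
        raise ValueError("assigned cells must carry a type label")
    vals = protein.values.reindex(mapped.index)
    grouped = vals.groupby([key["spot"], key["type"]], sort=True)
    means = grouped.mean()
    means.index.names = ["spot", "type"]
    coords = pos.reindex(mapped.index).groupby([key["spot"], key["type"]], sort=True).mean()
    meta = coords.copy()
    meta["n_cells"] = grouped.size()
    meta.index.names = ["spot", "type"]
    return means, meta


@dataclass
class LabelClassifier:
    """Linear multiclass SVM over scaled protein features, with a holdout report.

    ``holdout_f1`` maps class name -> F1 on a stratified holdout split of the
    pivot cells; it is an honesty check on the label transfer, not part of
    the fit.
    """

    pipeline: Pipeline
    classes: list[str]
    holdout_f1: dict[str, float]
    holdout_fraction: float


def train_label_classifier(
    pivot_proteins: pd.DataFrame,
    pivot_labels: pd.Series,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> LabelClassifier:
    """Train the label-transfer SVM on pivot cells.

    Pivot cells are the subset of imaging cells with high-confidence
    cross-modality matches; their transferred labels seed annotation of the
    whole imaging dataset. Requires >= 2 classes with >= 5 pivots each. A
    stratified holdout yields per-class F1 scores; the final model is then
    refit on all pivots.
    """
    y = pivot_labels.reindex(pivot_proteins.index)
    if y.isna().any():
        raise ValueError("every pivot cell needs a label")
    class_counts = y.value_counts()
    if len(class_counts) < 2:
        raise ValueError("need at least 2 classes to train the label classifier")
    if (class_counts < 5).any():
        small = class_counts[class_counts < 5].index.tolist()
        raise ValueError(f"need at least 5 pivots per class; too few for {small}")
    X = pivot_proteins.to_numpy(dtype=float)

    def make_pipeline() -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=1.0, random_state=seed, max_iter=5000)),
        ])

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y.to_numpy(), test_size=holdout_fraction, random_state=seed, stratify=y.to_numpy()
    )
    probe = make_pipeline().fit(X_tr, y_tr)
    pred = probe.predict(X_te)
    classes = sorted(class_counts.index)
    f1 = f1_score(y_te, pred, labels=classes, average=None, zero_division=0)
    final = make_pipeline().fit(X, y.to_numpy())
    return LabelClassifier(
        pipeline=final,
        classes=list(final.named_steps["svm"].classes_),
        holdout_f1={c: float(v) for c, v in zip(classes, f1)},
        holdout_fraction=holdout_fraction,
    )


def predict_labels(classifier: LabelClassifier, proteins: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Predict types for cells from their protein profiles.

    Returns the argmax labels and per-class scores (softmax over the SVM
    decision values — a monotone calibration for reporting only; the labels
    come from the raw decision function).
    """
    X = proteins.to_numpy(dtype=float)
    labels = pd.Series(classifier.pipeline.predict(X), index=proteins.index, name="label")
    dec = classifier.pipeline.decision_function(X)
    if dec.ndim == 1:  # binary: expand to two columns
        dec = np.column_stack([-dec, dec])
    z = dec - dec.max(axis=1, keepdims=True)
    soft = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    scores = pd.DataFrame(soft, index=proteins.index, columns=classifier.classes)
    return labels, scores


def export_wnn_inputs(subspots: SubSpotMatrix, outdir) -> dict:
    """Write paired RNA / protein sub-spot matrices for multimodal integration.

    Emits, under ``outdir``: the RNA side as MatrixMarket (genes x sub-spots,
    genes-in-rows on disk) with features/barcodes sidecars, the protein side
    and the metadata as CSV — all with identical row (sub-spot) order.
    Sub-spots lacking a protein partner are excluded and counted.
    """
    from pathlib import Path

    from .io import write_gene_spot_matrix

    if subspots.protein is None or subspots.meta is None:
        raise ValueError("sub-spot matrix has no protein aggregates; run aggregate_protein_subspots first")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    common = subspots.x.index.intersection(subspots.protein.index)
    n_excluded = len(subspots.x) - len(common)
    rna = subspots.x.loc[common]
    prot = subspots.protein.loc[common]
    meta = subspots.meta.loc[common]
    if not (rna.index.equals(prot.index) and rna.index.equals(meta.index)):
        raise ValueError("row-order mismatch between RNA, protein and metadata")
    ids = [f"{s}|{t}" for s, t in common]
    rna_flat = rna.copy()
    rna_flat.index = pd.Index(ids, name="subspot")
    write_gene_spot_matrix(rna_flat, outdir / "rna.mtx", outdir / "features.tsv", outdir / "barcodes.tsv")
    prot_flat = prot.copy()
    prot_flat.index = pd.Index(ids, name="subspot")
    prot_flat.to_csv(outdir / "protein.csv")
    meta_flat = meta.reset_index()
    meta_flat.insert(0, "subspot", ids)
    meta_flat.to_csv(outdir / "metadata.csv", index=False)
    report = {"n_subspots": len(common), "n_excluded_no_protein": int(n_excluded)}
    logger.info("exported %d paired sub-spots (%d without protein excluded)", len(common), n_excluded)
    return report
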