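"""Component predictors and their fusion into a single catalytic score.

Four per-residue predictors are combined:

* two RBF-kernel SVM feature predictors (structural and sequence), trained
  on scaled feature vectors with 1:6 positive:negative subsampling and
  Platt-calibrated probability outputs;
* two template predictors that transfer the catalytic annotation of the
  top-ranked template (by structure- or profile-alignment similarity) onto
  aligned query positions as binary scores.

Within each information channel the feature and template scores are merged
by a cutoff-gated convex combination,

    hunter = w * fscore + (1 - w) * tscore   if best_similarity >= cutoff
    hunter = fscore                          otherwise,

(weights alpha=0.55 / beta=0.57, cutoffs 0.6 / 0.87 for the structural and
sequence channels) — the template channel is suppressed when no reliable
template exists.  The two channels are finally blended with equal weight
(gamma=0.5) into the fused catalytic score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .dt_features import PairWeightMatrix, me_score, pair_frequency, network_features, train_pair_weights
from .laplacian_features import SCALE_QUANTILES, laplacian_norms, scale_factors
from .sequence_features import (
    PSSM,
    ConservationProfile,
    catalytic_propensity,
    static_features,
    window_features,
)
from .structure_model import CatalyticAnnotation, Structure
from .tessellation import (
    DEFAULT_FACET_CUTOFF,
    ResidueContactGraph,
    contact_graph,
    microenvironment,
    tessellate,
)

__all__ = [
    "SCORE_COLUMNS",
    "SVMConfig",
    "FusionConfig",
    "TemplateHit",
    "ScalingStats",
    "FeatureSVM",
    "QueryRecord",
    "FeatureCache",
    "CRHunterModel",
    "scale_features",
    "build_structural_vectors",
    "build_sequence_vectors",
    "train_feature_predictor",
    "template_predict",
    "fuse",
    "crhunter_score",
    "read_template_hits",
    "write_template_hits",
    "scores_to_frame",
]

#: Order of the per-residue score columns emitted by the full model.
SCORE_COLUMNS = [
    "fscore_str",
    "tscore_str",
    "fscore_seq",
    "tscore_seq",
    "strhunter",
    "seqhunter",
    "crhunter",
]

#: Sentinel similarity reported when a template channel has no hits.
NO_TEMPLATE = float("-inf")


@dataclass(frozen=True)
class SVMConfig:
    """Feature-predictor hyperparameters.

    Defaults are the published operating point: C=2, RBF gamma=0.03125,
    1:6 positive:negative training ratio, structural window of 4 contact
    neighbors and sequence half-width of 9 (19 positions).
    """

    C: float = 2.0
    rbf_gamma: float = 0.03125
    neg_pos_ratio: float = 6.0
    window_structure: int = 4
    window_sequence: int = 9
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0 or self.rbf_gamma <= 0:
            raise ValueError("C and rbf_gamma must be positive")
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be >= 1")
        if self.window_structure < 0 or self.window_sequence < 0:
            raise ValueError("windows must be non-negative")


@dataclass(frozen=True)
class FusionConfig:
    """Fusion weights and template-reliability cutoffs (published values)."""

    alpha: float = 0.55
    sp_cutoff: float = 0.6
    beta: float = 0.57
    hh_cutoff: float = 0.87
    gamma: float = 0.5

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("sp_cutoff", "hh_cutoff"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class TemplateHit:
    """One alignment hit: template id, similarity, query->template mapping."""

    template_id: str
    similarity: float
    mapping: dict[int, int]

    def __post_init__(self):
        if not math.isfinite(self.similarity):
            raise ValueError("similarity must be finite")
        values = list(self.mapping.values())
        if len(set(values)) != len(values):
            raise ValueError(f"{self.template_id}: mapping is not injective")


@dataclass
class ScalingStats:
    """Frozen training statistics for :func:`scale_features`."""

    mean: pd.Series
    std: pd.Series
    pssm_columns: frozenset[str]
    binary_columns: frozenset[str]
    columns: list[str]


def _logistic(x):
    # clamp away from 0/1 so outputs stay in the open interval even when
    # the exponential saturates in double precision
    with np.errstate(over="ignore"):
        value = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
    return np.clip(value, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def scale_features(
    table: pd.DataFrame,
    pssm_columns: Iterable[str],
    binary_columns: Iterable[str],
    stats: ScalingStats | None = None,
) -> tuple[pd.DataFrame, ScalingStats]:
    """Map every non-binary feature into (0, 1).

    PSSM columns pass through the logistic function directly; remaining
    non-binary columns are Z-scored with training statistics (computed here
    when ``stats`` is None, reused verbatim at prediction time) and then
    squashed by the logistic; binary columns are untouched.  Zero-variance
    columns map to the constant 0.5.
    """
    pssm_columns = frozenset(pssm_columns)
    binary_columns = frozenset(binary_columns)
    unknown = (pssm_columns | binary_columns) - set(table.columns)
    if unknown:
        raise ValueError(f"unknown columns in scaling sets: {sorted(unknown)}")
    other = [c for c in table.columns if c not in pssm_columns and c not in binary_columns]
    if stats is None:
        mean = table[other].mean()
        std = table[other].std(ddof=0)
        stats = ScalingStats(mean, std, pssm_columns, binary_columns, list(table.columns))
    else:
        if list(table.columns) != stats.columns:
            raise ValueError("feature columns differ from the training layout")
    scaled = table.copy()
    for c in pssm_columns:
        scaled[c] = _logistic(table[c].to_numpy(dtype=float))
    for c in other:
        sd = stats.std[c]
        if sd == 0 or not math.isfinite(sd):
            scaled[c] = 0.5
        else:
            scaled[c] = _logistic((table[c].to_numpy(dtype=float) - stats.mean[c]) / sd)
    return scaled, stats


def build_structural_vectors(
    scaled_table: pd.DataFrame,
    graph: ResidueContactGraph,
    window: int = 4,
    cutoff: int = DEFAULT_FACET_CUTOFF,
) -> np.ndarray:
    """Per-residue structural vectors: target block plus top contact neighbors.

    The ``window`` highest-facet-count microenvironment neighbors (ties by
    residue index) contribute their feature blocks after the target's own;
    missing neighbors are zero-padded, each neighbor slot carrying a
    padding-indicator bit.  Shape: (n, f + window * (f + 1)).
    """
    values = scaled_table.to_numpy(dtype=float)
    n, f = values.shape
    if n != graph.n_residues:
        raise ValueError("feature table and contact graph disagree on residue count")
    out = np.zeros((n, f + window * (f + 1)))
    for i in range(n):
        parts = [values[i]]
        neighbors = microenvironment(graph, i, cutoff)[:window]
        for j, _count in neighbors:
            parts.append(np.append(values[j], 0.0))
        for _ in range(window - len(neighbors)):
            parts.append(np.append(np.zeros(f), 1.0))
        out[i] = np.concatenate(parts)
    return out


def build_sequence_vectors(scaled_table: pd.DataFrame, half_width: int = 9) -> np.ndarray:
    """Sliding-window sequence vectors for every residue."""
    n = len(scaled_table)
    values = scaled_table.to_numpy(dtype=float)
    return np.stack([window_features(values, i, half_width) for i in range(n)])


@dataclass
class FeatureSVM:
    """A trained, Platt-calibrated SVM feature predictor."""

    model: object  # calibrated classifier exposing predict_proba/classes_
    training_indices: np.ndarray

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        """Probability of the catalytic class for each row."""
        proba = self.model.predict_proba(np.asarray(vectors, dtype=float))
        positive = int(np.where(self.model.classes_ == 1)[0][0])
        return proba[:, positive]


def train_feature_predictor(
    vectors: np.ndarray, labels: np.ndarray, config: SVMConfig
) -> FeatureSVM:
    """Subsample negatives to the configured ratio and fit the RBF SVM.

    The negative subsample is drawn uniformly at random with the config
    seed, so identical seeds give identical subsample indices and
    (platform-fixed) identical predictions.  Probabilities come from Platt
    (sigmoid) calibration over 5 deterministic internal folds.

    Raises
    ------
    ValueError
        If the training set has no positive example.
    """
    from sklearn.calibration import CalibratedClassifierCV

    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0:
        raise ValueError("training set has no positive example")
    rng = np.random.default_rng(config.seed)
    keep = min(len(neg), int(round(config.neg_pos_ratio * len(pos))))
    chosen_neg = rng.choice(neg, size=keep, replace=False) if keep else np.array([], dtype=int)
    selected = np.sort(np.concatenate([pos, chosen_neg]))
    svc = SVC(C=config.C, kernel="rbf", gamma=config.rbf_gamma, random_state=config.seed)
    calibrated = CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    calibrated.fit(vectors[selected], labels[selected])
    return FeatureSVM(model=calibrated, training_indices=selected)


def template_predict(
    query_length: int,
    hits: Sequence[TemplateHit],
    template_annotations: Mapping[str, frozenset[int] | set[int] | CatalyticAnnotation],
    template_lengths: Mapping[str, int] | None = None,
) -> tuple[np.ndarray, float]:
    """Transfer the top template's catalytic annotation onto the query.

    Hits are ranked by similarity descending (ties by template id); a query
    position scores 1 iff it maps onto an annotated catalytic residue of
    the best template, 0 otherwise (unaligned positions included).  An
    empty hit list yields all zeros with a ``-inf`` sentinel similarity.
    """
    scores = np.zeros(query_length)
    if not hits:
        return scores, NO_TEMPLATE
    top = sorted(hits, key=lambda h: (-h.similarity, h.template_id))[0]
    annotation = template_annotations[top.template_id]
    catalytic = (
        annotation.catalytic_indices
        if isinstance(annotation, CatalyticAnnotation)
        else frozenset(annotation)
    )
    length = template_lengths.get(top.template_id) if template_lengths else None
    for qpos, tpos in top.mapping.items():
        if not 0 <= qpos < query_length:
            raise IndexError(f"query position {qpos} outside 0..{query_length - 1}")
        if tpos < 0 or (length is not None and tpos >= length):
            raise IndexError(f"template position {tpos} outside template {top.template_id}")
        if tpos in catalytic:
            scores[qpos] = 1.0
    return scores, float(top.similarity)


def fuse(
    fscore: np.ndarray,
    tscore: np.ndarray,
    best_similarity: float,
    weight: float,
    cutoff: float,
) -> np.ndarray:
    """Cutoff-gated convex combination of feature and template scores.

    Below the similarity cutoff the template channel is unreliable and the
    feature score is returned unchanged.
    """
    fscore = np.asarray(fscore, dtype=float)
    tscore = np.asarray(tscore, dtype=float)
    if fscore.shape != tscore.shape:
        raise ValueError("feature and template score vectors differ in length")
    if best_similarity >= cutoff:
        return weight * fscore + (1.0 - weight) * tscore
    return fscore.copy()


def crhunter_score(str_fused: np.ndarray, seq_fused: np.ndarray, gamma: float = 0.5) -> np.ndarray:
    """Equal-weight (by default) blend of the two channel scores."""
    str_fused = np.asarray(str_fused, dtype=float)
    seq_fused = np.asarray(seq_fused, dtype=float)
    if str_fused.shape != seq_fused.shape:
        raise ValueError("channel score vectors differ in length")
    return gamma * str_fused + (1.0 - gamma) * seq_fused


# ---------------------------------------------------------------------------
# end-to-end model


@dataclass
class QueryRecord:
    """All inputs for one query chain."""

    structure: Structure
    pssm: PSSM
    conservation: ConservationProfile
    annotation: CatalyticAnnotation | None = None
    str_hits: list[TemplateHit] = field(default_factory=list)
    seq_hits: list[TemplateHit] = field(default_factory=list)
    msa: list[str] | None = None  # aligned rows, query first (kept for round-trips)

    @property
    def id(self) -> str:
        return self.structure.id


class FeatureCache:
    """Memoizes the fold-independent feature channels of each record.

    Tessellation, contact graph, pair-frequency matrices, network features,
    Laplacian norms and PSSM/conservation/static tables depend only on the
    record, not on the training fold, so cross-validation reuses them; only
    the microenvironment-score column (which needs a fold-trained weight
    matrix) and the catalytic-propensity column are recomputed per fold.
    """

    def __init__(self, facet_cutoff: int = DEFAULT_FACET_CUTOFF):
        self.facet_cutoff = facet_cutoff
        self._graphs: dict[str, ResidueContactGraph] = {}
        self._pair_freqs: dict[str, np.ndarray] = {}
        self._str_base: dict[str, pd.DataFrame] = {}
        self._seq_base: dict[str, pd.DataFrame] = {}

    def graph(self, record: QueryRecord) -> ResidueContactGraph:
        if record.id not in self._graphs:
            tess = tessellate(record.structure)
            self._graphs[record.id] = contact_graph(record.structure, tess)
        return self._graphs[record.id]

    def pair_freqs(self, record: QueryRecord) -> np.ndarray:
        if record.id not in self._pair_freqs:
            graph = self.graph(record)
            self._pair_freqs[record.id] = np.stack(
                [
                    pair_frequency(record.structure, graph, i, self.facet_cutoff)
                    for i in range(len(record.structure))
                ]
            )
        return self._pair_freqs[record.id]

    def structural_base(self, record: QueryRecord) -> pd.DataFrame:
        """Network + Laplacian + PSSM columns (everything but me_score)."""
        if record.id not in self._str_base:
            graph = self.graph(record)
            net = network_features(graph, self.facet_cutoff)
            lns = laplacian_norms(record.structure, scale_factors(record.structure))
            ln_cols = pd.DataFrame(
                lns, columns=[f"ln_q{k}" for k in range(len(SCALE_QUANTILES))]
            )
            pssm = record.pssm.to_frame()
            if not (len(net) == len(ln_cols) == len(pssm) == len(record.structure)):
                raise ValueError(f"{record.id}: feature channels disagree on residue count")
            base = pd.concat(
                [net.reset_index(drop=True), ln_cols, pssm.reset_index(drop=True)], axis=1
            )
            self._str_base[record.id] = base
        return self._str_base[record.id]

    def sequence_base(self, record: QueryRecord) -> pd.DataFrame:
        """PSSM + conservation + static columns (everything but propensity)."""
        if record.id not in self._seq_base:
            pssm = record.pssm.to_frame().reset_index(drop=True)
            cons = record.conservation.to_frame().reset_index(drop=True)
            static = static_features(record.structure.sequence).reset_index(drop=True)
            static = static.drop(columns=["cat_propensity"])
            if not (len(pssm) == len(cons) == len(static)):
                raise ValueError(f"{record.id}: sequence channels disagree on residue count")
            self._seq_base[record.id] = pd.concat([pssm, cons, static], axis=1)
        return self._seq_base[record.id]


def _pssm_cols(table: pd.DataFrame) -> frozenset[str]:
    return frozenset(c for c in table.columns if c.startswith("pssm_"))


def _binary_cols(table: pd.DataFrame) -> frozenset[str]:
    return frozenset(c for c in table.columns if c.startswith("is_"))


@dataclass
class CRHunterModel:
    """The fitted four-predictor ensemble.

    Holds the trained pair-weight matrix, catalytic-propensity table,
    scaling statistics, both SVMs, the template annotation library and all
    configuration needed to score a new query.
    """

    version: str
    svm_config: SVMConfig
    fusion_config: FusionConfig
    facet_cutoff: int
    w_dt: PairWeightMatrix
    propensity: dict[str, float]
    str_scaler: ScalingStats
    seq_scaler: ScalingStats
    str_svm: FeatureSVM
    seq_svm: FeatureSVM
    template_annotations: dict[str, frozenset[int]]

    # -- training -----------------------------------------------------------

    @classmethod
    def fit(
        cls,
        records: Sequence[QueryRecord],
        template_annotations: Mapping[str, frozenset[int] | set[int]] | None = None,
        svm_config: SVMConfig | None = None,
        fusion_config: FusionConfig | None = None,
        facet_cutoff: int = DEFAULT_FACET_CUTOFF,
        cache: FeatureCache | None = None,
    ) -> "CRHunterModel":
        """Train every fold-dependent component on annotated records."""
        svm_config = svm_config or SVMConfig()
        fusion_config = fusion_config or FusionConfig()
        cache = cache or FeatureCache(facet_cutoff)
        if cache.facet_cutoff != facet_cutoff:
            raise ValueError("cache facet cutoff differs from model facet cutoff")
        missing = [r.id for r in records if r.annotation is None]
        if missing:
            raise ValueError(f"records without annotations cannot train: {missing}")

        w_dt = train_pair_weights(
            [(r.structure, cache.graph(r), r.annotation) for r in records],
            cutoff=facet_cutoff,
        )
        propensity = catalytic_propensity(
            (r.structure.sequence, r.annotation) for r in records
        )

        str_tables = [cls._structural_table(r, cache, w_dt) for r in records]
        seq_tables = [cls._sequence_table(r, cache, propensity) for r in records]
        labels = np.concatenate([r.annotation.labels(len(r.structure)) for r in records])

        _, str_scaler = scale_features(
            pd.concat(str_tables, ignore_index=True),
            _pssm_cols(str_tables[0]),
            _binary_cols(str_tables[0]),
        )
        _, seq_scaler = scale_features(
            pd.concat(seq_tables, ignore_index=True),
            _pssm_cols(seq_tables[0]),
            _binary_cols(seq_tables[0]),
        )

        str_vectors = np.vstack(
            [
                build_structural_vectors(
                    scale_features(t, str_scaler.pssm_columns, str_scaler.binary_columns, str_scaler)[0],
                    cache.graph(r),
                    svm_config.window_structure,
                    facet_cutoff,
                )
                for r, t in zip(records, str_tables)
            ]
        )
        seq_vectors = np.vstack(
            [
                build_sequence_vectors(
                    scale_features(t, seq_scaler.pssm_columns, seq_scaler.binary_columns, seq_scaler)[0],
                    svm_config.window_sequence,
                )
                for r, t in zip(records, seq_tables)
            ]
        )

        str_svm = train_feature_predictor(str_vectors, labels, svm_config)
        seq_svm = train_feature_predictor(seq_vectors, labels, svm_config)

        annotations = {
            tid: frozenset(indices) for tid, indices in (template_annotations or {}).items()
        }
        return cls(
            version="1",
            svm_config=svm_config,
            fusion_config=fusion_config,
            facet_cutoff=facet_cutoff,
            w_dt=w_dt,
            propensity=propensity,
            str_scaler=str_scaler,
            seq_scaler=seq_scaler,
            str_svm=str_svm,
            seq_svm=seq_svm,
            template_annotations=annotations,
        )

    @staticmethod
    def _structural_table(
        record: QueryRecord, cache: FeatureCache, w_dt: PairWeightMatrix
    ) -> pd.DataFrame:
        base = cache.structural_base(record)
        me = np.array([me_score(f, w_dt) for f in cache.pair_freqs(record)])
        table = base.copy()
        table.insert(0, "me_score", me)
        return table

    @staticmethod
    def _sequence_table(
        record: QueryRecord, cache: FeatureCache, propensity: Mapping[str, float]
    ) -> pd.DataFrame:
        table = cache.sequence_base(record).copy()
        table["cat_propensity"] = [propensity[a] for a in record.structure.sequence]
        return table

    # -- prediction ---------------------------------------------------------

    def predict(
        self,
        record: QueryRecord,
        cache: FeatureCache | None = None,
        exclude_template_ids: Iterable[str] = (),
    ) -> pd.DataFrame:
        """Score every residue of a query with all seven predictors.

        ``exclude_template_ids`` drops template hits (e.g. a test fold's
        own structures during cross-validation) before top-hit selection.
        Returns a DataFrame with :data:`SCORE_COLUMNS`; the best template
        similarities are stored in ``result.attrs``.
        """
        cache = cache or FeatureCache(self.facet_cutoff)
        excluded = set(exclude_template_ids)
        n = len(record.structure)

        str_table = self._structural_table(record, cache, self.w_dt)
        str_scaled, _ = scale_features(
            str_table, self.str_scaler.pssm_columns, self.str_scaler.binary_columns, self.str_scaler
        )
        fscore_str = self.str_svm.predict(
            build_structural_vectors(
                str_scaled, cache.graph(record), self.svm_config.window_structure, self.facet_cutoff
            )
        )

        seq_table = self._sequence_table(record, cache, self.propensity)
        seq_scaled, _ = scale_features(
            seq_table, self.seq_scaler.pssm_columns, self.seq_scaler.binary_columns, self.seq_scaler
        )
        fscore_seq = self.seq_svm.predict(
            build_sequence_vectors(seq_scaled, self.svm_config.window_sequence)
        )

        str_hits = [h for h in record.str_hits if h.template_id not in excluded]
        seq_hits = [h for h in record.seq_hits if h.template_id not in excluded]
        tscore_str, best_sp = template_predict(n, str_hits, self.template_annotations)
        tscore_seq, best_hh = template_predict(n, seq_hits, self.template_annotations)

        fc = self.fusion_config
        strhunter = fuse(fscore_str, tscore_str, best_sp, fc.alpha, fc.sp_cutoff)
        seqhunter = fuse(fscore_seq, tscore_seq, best_hh, fc.beta, fc.hh_cutoff)
        fused = crhunter_score(strhunter, seqhunter, fc.gamma)

        result = pd.DataFrame(
            {
                "fscore_str": fscore_str,
                "tscore_str": tscore_str,
                "fscore_seq": fscore_seq,
                "tscore_seq": tscore_seq,
                "strhunter": strhunter,
                "seqhunter": seqhunter,
                "crhunter": fused,
            },
            index=pd.RangeIndex(n, name="residue"),
        )
        result.attrs["best_sp"] = best_sp
        result.attrs["best_hh"] = best_hh
        result.attrs["structure_id"] = record.id
        return result

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "CRHunterModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a {cls.__name__}")
        return model


# ---------------------------------------------------------------------------
# template-hit and score TSV dialects


def write_template_hits(hits_by_query: Mapping[str, Sequence[TemplateHit]], path: str | Path) -> None:
    """Write hits as TSV: query_id, template_id, similarity, q:t pair list."""
    with open(path, "w") as handle:
        handle.write("query_id\ttemplate_id\tsimilarity\tmapping\n")
        for query_id in sorted(hits_by_query):
            for hit in hits_by_query[query_id]:
                pairs = ",".join(f"{q}:{t}" for q, t in sorted(hit.mapping.items()))
                handle.write(f"{query_id}\t{hit.template_id}\t{hit.similarity:.6f}\t{pairs}\n")


def read_template_hits(path: str | Path) -> dict[str, list[TemplateHit]]:
    """Read the TSV written by :func:`write_template_hits`."""
    hits: dict[str, list[TemplateHit]] = {}
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("query_id"):
            raise ValueError(f"{path}: missing template-hit header")
        for lineno, raw in enumerate(handle, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path} line {lineno}: expected 4 columns")
            query_id, template_id, sim, mapping_field = parts
            mapping: dict[int, int] = {}
            if mapping_field.strip():
                for token in mapping_field.split(","):
                    q, t = token.split(":")
                    mapping[int(q)] = int(t)
            hits.setdefault(query_id, []).append(
                TemplateHit(template_id=template_id, similarity=float(sim), mapping=mapping)
            )
    for query_id in hits:
        hits[query_id].sort(key=lambda h: (-h.similarity, h.template_id))
    return hits


def scores_to_frame(structure: Structure, scores: pd.DataFrame) -> pd.DataFrame:
    """Attach residue index and amino acid to a score table for TSV export."""
    out = scores.copy()
    out.insert(0, "aa", list(structure.sequence))
    out.index.name = "residue"
    return out
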