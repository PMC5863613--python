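"""Database generation, splitting, PCA training selection, and scaling.

A database row holds the flattened Hamiltonian (features ``h_0 ... h_{n^2-1}``),
the transfer time and efficiency computed by an engine, the per-record seed,
the engine tag and a split tag.  Training sets are either drawn at random
from the pool or picked by greedy farthest-point selection in a reduced
principal-component space, which favours the most diverse Hamiltonians when
the sampled transfer properties are strongly non-uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .hamiltonian import (BathParameters, SamplingRanges, SinkParameters,
                          flatten, sample_hamiltonian)
from .dynamics import NoTransferError
from .heom import ConvergenceError, ResourceError, converged_transfer_time
from .redfield import redfield_transfer_statistics

logger = logging.getLogger("eetml")

__all__ = [
    "build_database",
    "split_dataset",
    "PCAFarthestPointSelector",
    "pca_select",
    "ScalerPair",
    "fit_scalers",
    "feature_columns",
    "save_database",
    "load_database",
    "load_external_database",
]


def feature_columns(n_sites: int) -> list[str]:
    return [f"h_{i}" for i in range(n_sites * n_sites)]


def _label_with_engine(h, engine, bath, sink, heom_kwargs):
    if engine == "redfield":
        return redfield_transfer_statistics(h, bath, sink)
    if engine == "heom":
        stats, _ = converged_transfer_time(h, bath, sink, **heom_kwargs)
        return stats
    raise ValueError(f"unknown engine '{engine}'")


def build_database(ranges: SamplingRanges, n: int, engine: str,
                   bath: BathParameters, sink: SinkParameters, seed: int,
                   heom_kwargs: dict | None = None) -> pd.DataFrame:
    """Sample ``n`` Hamiltonians and label them with one engine.

    Record ``i`` uses seed ``seed + i`` so any row can be regenerated in
    isolation.  Records whose dynamics fail (no transfer, no hierarchy
    convergence) are logged and excluded; their seeds are kept in
    ``df.attrs['failed_seeds']``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    heom_kwargs = heom_kwargs or {}
    logger.info("building database: label=%s n=%d engine=%s seed=%d "
                "donor=%d acceptor=%d gamma_trap=%.3g/ps gamma_loss=%.3g/ps "
                "lambda=%.3g nu=%.4g T=%.5g",
                ranges.label, n, engine, seed, sink.donor_index + 1,
                sink.acceptor_index + 1, sink.gamma_trap, sink.gamma_loss,
                bath.lambda_reorg, bath.nu, bath.temperature)
    cols = feature_columns(ranges.n_sites)
    rows, failed = [], []
    for i in range(n):
        record_seed = seed + i
        h = sample_hamiltonian(ranges, record_seed)
        try:
            stats = _label_with_engine(h, engine, bath, sink, heom_kwargs)
        except (NoTransferError, ConvergenceError, ResourceError) as exc:
            logger.warning("record seed %d failed: %s", record_seed, exc)
            failed.append(record_seed)
            continue
        row = dict(zip(cols, flatten(h)))
        row.update(transfer_time_ps=stats.transfer_time_ps,
                   efficiency=stats.efficiency, engine=engine,
                   seed=record_seed, split="pool")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["failed_seeds"] = failed
    df.attrs["label"] = ranges.label
    return df


def split_dataset(records: pd.DataFrame, n_valid: int, n_test: int,
                  seed: int) -> pd.DataFrame:
    """Tag rows as pool/valid/test with a uniform random disjoint split."""
    total = len(records)
    if n_valid + n_test >= total and (n_valid or n_test):
        raise ValueError("n_valid + n_test must be smaller than the database")
    rng = np.random.default_rng(seed)
    order = rng.permutation(total)
    split = np.array(["pool"] * total, dtype=object)
    split[order[:n_valid]] = "valid"
    split[order[n_valid:n_valid + n_test]] = "test"
    out = records.copy()
    out["split"] = split
    out.attrs = dict(records.attrs)
    return out


class PCAFarthestPointSelector(BaseEstimator):
    """Greedy max-min training selection in a reduced PCA space.

    Features are standardized, projected onto the smallest number of
    principal components explaining at least ``variance_fraction`` of the
    variance, and then picked greedily: start from the point farthest from
    the pool centroid, then repeatedly add the point whose minimum distance
    to the selected set is largest (ties broken by lowest index).  This is
    the classic 2-approximation heuristic for the dispersion problem, not
    an exact optimizer.
    """

    def __init__(self, variance_fraction: float = 0.95):
        self.variance_fraction = variance_fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0.0] = 1.0
        self.scale_ = std
        z = (X - self.mean_) / self.scale_
        pca = PCA(svd_solver="full", random_state=0)
        scores = pca.fit_transform(z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_comp = int(np.searchsorted(cum, self.variance_fraction) + 1)
        n_comp = min(n_comp, scores.shape[1])
        self.n_components_ = n_comp
        self.embedding_ = scores[:, :n_comp]
        self.pca_ = pca
        return self

    def select(self, k: int) -> np.ndarray:
        """Indices of ``k`` maximally separated pool points."""
        emb = self.embedding_
        n = emb.shape[0]
        if not 1 <= k <= n:
            raise ValueError("k must be between 1 and the pool size")
        if k == n:
            return np.arange(n)
        centroid = emb.mean(axis=0)
        first = int(np.argmax(np.linalg.norm(emb - centroid, axis=1)))
        chosen = [first]
        min_dist = np.linalg.norm(emb - emb[first], axis=1)
        for _ in range(k - 1):
            nxt = int(np.argmax(min_dist))
            chosen.append(nxt)
            np.minimum(min_dist, np.linalg.norm(emb - emb[nxt], axis=1),
                       out=min_dist)
        return np.asarray(chosen)


def pca_select(features, k: int, variance_fraction: float = 0.95) -> np.ndarray:
    """Functional wrapper around :class:`PCAFarthestPointSelector`."""
    sel = PCAFarthestPointSelector(variance_fraction=variance_fraction)
    return sel.fit(features).select(k)


@dataclass
class ScalerPair:
    """Feature standardization and positive target scaling fitted on train.

    Features are shifted/scaled to zero mean and unit variance per
    dimension (zero-variance dimensions pass through); targets are divided
    by their training means, which preserves positivity.
    """

    feature_mean: np.ndarray
    feature_scale: np.ndarray
    target_scale: np.ndarray

    def transform_features(self, X):
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale

    def inverse_features(self, Z):
        return np.asarray(Z, dtype=float) * self.feature_scale + self.feature_mean

    def transform_targets(self, y):
        return np.asarray(y, dtype=float) / self.target_scale

    def inverse_targets(self, z):
        return np.asarray(z, dtype=float) * self.target_scale

    def to_dict(self):
        return {"feature_mean": self.feature_mean.tolist(),
                "feature_scale": self.feature_scale.tolist(),
                "target_scale": self.target_scale.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(feature_mean=np.asarray(d["feature_mean"]),
                   feature_scale=np.asarray(d["feature_scale"]),
                   target_scale=np.asarray(d["target_scale"]))


def fit_scalers(features, targets) -> ScalerPair:
    """Fit a :class:`ScalerPair` on training features and positive targets."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training records")
    std = X.std(axis=0)
    std[std == 0.0] = 1.0
    scale = y.mean(axis=0)
    if np.any(scale <= 0):
        raise ValueError("target means must be positive")
    return ScalerPair(feature_mean=X.mean(axis=0), feature_scale=std,
                      target_scale=scale)


def save_database(df: pd.DataFrame, path) -> None:
    """Write CSV (default) or JSON-lines when the suffix is .jsonl."""
    path = str(path)
    if path.endswith(".jsonl"):
        df.to_json(path, orient="records", lines=True)
    else:
        df.to_csv(path, index=False)


def load_database(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".jsonl"):
        return pd.read_json(path, orient="records", lines=True)
    return pd.read_csv(path)


def load_external_database(path, column_mapping: dict,
                           engine: str = "heom") -> pd.DataFrame:
    """Adapt a third-party table of labelled Hamiltonians to this schema.

    ``column_mapping`` maps this package's column names (``h_0`` ...,
    ``transfer_time_ps``, ``efficiency``) to the names used in the external
    file; unmapped metadata columns are dropped.
    """
    raw = load_database(path)
    out = pd.DataFrame({ours: raw[theirs] for ours, theirs in
                        column_mapping.items()})
    if "transfer_time_ps" not in out or "efficiency" not in out:
        raise ValueError("mapping must provide transfer_time_ps and efficiency")
    out["engine"] = engine
    out["seed"] = -1
    out["split"] = "pool"
    return out
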