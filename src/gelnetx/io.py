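"""Tabular input/output: expression matrices and run configuration."""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd

from .network import Network

logger = logging.getLogger(__name__)

__all__ = ["read_expression_matrix", "write_expression_matrix",
           "config_hash", "write_config"]


def read_expression_matrix(path, features_in_rows: bool = True,
                           network: Network | None = None, sep: str = "\t"):
    """Read a features-by-samples (default) or samples-by-features table.

    The file must have a header row of sample ids and a first column of
    feature ids.  When a network is supplied, features absent from it are
    dropped (with a logged count) and the matrix keeps its own feature
    order, mirroring the usual reduction of an expression dataset to the
    genes of an interaction network.

    Returns ``(X, feature_ids, sample_ids)`` with X of shape
    (n_samples, n_features).
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate feature ids in expression matrix")
    if not features_in_rows:
        df = df.T
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cells in expression matrix: {err}")
    feature_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    if network is not None:
        keep = [i for i, g in enumerate(feature_ids)
                if g in set(network.node_ids)]
        dropped = len(feature_ids) - len(keep)
        if dropped:
            logger.warning("dropping %d feature(s) absent from the network",
                           dropped)
        X = X[keep]
        feature_ids = [feature_ids[i] for i in keep]
    return X.T.copy(), feature_ids, sample_ids


def write_expression_matrix(path, X, feature_ids, sample_ids,
                            features_in_rows: bool = True,
                            sep: str = "\t") -> None:
    X = np.asarray(X, float)  # (n_samples, n_features)
    df = pd.DataFrame(X.T, index=feature_ids, columns=sample_ids)
    if not features_in_rows:
        df = df.T
    df.to_csv(path, sep=sep, float_format="%.10g")


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_config(path, config: dict) -> str:
    h = config_hash(config)
    payload = dict(config)
    payload["config_hash"] = h
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
    return h
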