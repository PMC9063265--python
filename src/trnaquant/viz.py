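"""Plot-ready data for the four result views, plus thin matplotlib renderers.

The testable surface is the data tables: sample MDS coordinates from
classical (Torgerson) scaling of leading-log-fold-change distances, a
volcano table (log2 fold change vs -log10 adjusted p with up/down/ns
status), significant-isodecoder counts per anticodon, and significant-
isoacceptor counts per amino acid.  Rendering just draws those tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import parse_gene_name
from .destats import DETable


@dataclass
class MdsResult:
    coordinates: pd.DataFrame   # samples x (dim1, dim2)
    eigenvalues: np.ndarray
    distances: pd.DataFrame     # samples x samples, symmetric, zero diagonal


def mds_coordinates(log_cpm: pd.DataFrame, top_k: int = 500) -> MdsResult:
    """Classical MDS of samples on leading-log-fold-change distances.

    The distance between two samples is the root mean square of the
    ``top_k`` largest absolute per-gene log-CPM differences for that pair
    (all genes when fewer are available), the convention used for
    RNA-seq sample similarity plots.
    """
    samples = list(log_cpm.columns)
    n = len(samples)
    if n < 3:
        raise ValueError("MDS requires at least three samples")
    x = log_cpm.to_numpy(dtype=float)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(x[:, i] - x[:, j])
            k = min(top_k, diff.size)
            top = np.partition(diff, diff.size - k)[diff.size - k:]
            dist[i, j] = dist[j, i] = float(np.sqrt(np.mean(top**2)))
    # Torgerson double-centering of squared distances
    d2 = dist**2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ d2 @ j_mat
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, 2))
    for dim in range(2):
        lam = max(evals[dim], 0.0)
        vec = evecs[:, dim] * np.sqrt(lam)
        nz = np.nonzero(np.abs(vec) > 1e-12)[0]
        if nz.size and vec[nz[0]] < 0:  # deterministic sign convention
            vec = -vec
        coords[:, dim] = vec
    return MdsResult(
        coordinates=pd.DataFrame(coords, index=samples, columns=["dim1", "dim2"]),
        eigenvalues=evals,
        distances=pd.DataFrame(dist, index=samples, columns=samples),
    )


def volcano_data(
    de: DETable, fc_threshold: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-entity (log2_fc, -log10 adjusted p, status in {up, down, ns})."""
    t = de.table
    if t.empty:
        return pd.DataFrame(columns=["log2_fc", "neg_log10_p", "status"])
    status = np.where(
        t["significant"] & (t["log2_fc"] > 0), "up",
        np.where(t["significant"] & (t["log2_fc"] < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "log2_fc": t["log2_fc"],
            "neg_log10_p": -np.log10(t["p_bh"].clip(lower=1e-300)),
            "status": status,
        },
        index=t.index,
    )


def anticodon_bar_data(de: DETable) -> pd.DataFrame:
    """Counts of significantly up/down isodecoders per (isotype, anticodon)."""
    if de.level != "isodecoder":
        raise ValueError("anticodon bar data requires an isodecoder-level table")
    return _signed_counts(de, lambda name: _family_key(name))


def aa_pyramid_data(de: DETable) -> pd.DataFrame:
    """Counts of significantly up/down isoacceptors per amino acid."""
    if de.level != "isoacceptor":
        raise ValueError("pyramid data requires an isoacceptor-level table")
    return _signed_counts(de, lambda name: _isotype_key(name))


def _family_key(name: str) -> str:
    # isodecoder names lack the copy field; re-add a dummy to reuse the parser
    iso, ac, _, _ = parse_gene_name(name + "-1")
    return f"{iso}-{ac}"


def _isotype_key(name: str) -> str:
    iso, _, _, _ = parse_gene_name(name + "-1-1")
    return iso


def _signed_counts(de: DETable, keyfn) -> pd.DataFrame:
    sig = de.table[de.table["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=["n_up", "n_down"])
    keys = [keyfn(name) for name in sig.index]
    up = sig["log2_fc"] > 0
    out = (
        pd.DataFrame({"key": keys, "n_up": up.to_numpy(), "n_down": (~up).to_numpy()})
        .groupby("key")[["n_up", "n_down"]]
        .sum()
        .astype(int)
        .sort_index()
    )
    out.index.name = None
    return out


# ---------------------------------------------------------------------------
# Thin renderers (matplotlib, Agg-safe)

def plot_mds(result: MdsResult, groups: dict[str, str] | None, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    coords = result.coordinates
    labels = [groups.get(s, "sample") if groups else "sample" for s in coords.index]
    for grp in sorted(set(labels)):
        sel = [lbl == grp for lbl in labels]
        ax.scatter(coords.loc[sel, "dim1"], coords.loc[sel, "dim2"], label=grp)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title("MDS of samples")
    if groups:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_volcano(data: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = {"up": "tab:red", "down": "tab:blue", "ns": "lightgray"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for status, sub in data.groupby("status"):
        ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=8,
                   c=colors.get(status, "black"), label=status)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_anticodon_bar(data: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(data))
    ax.bar(x, data["n_up"], color="tab:red", label="up")
    ax.bar(x, -data["n_down"], color="tab:blue", label="down")
    ax.set_xticks(x)
    ax.set_xticklabels(data.index, rotation=90, fontsize=7)
    ax.set_ylabel("significant isodecoders")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_aa_pyramid(data: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 6))
    y = np.arange(len(data))
    ax.barh(y, data["n_up"], color="tab:red", label="up")
    ax.barh(y, -data["n_down"], color="tab:blue", label="down")
    ax.set_yticks(y)
    ax.set_yticklabels(data.index)
    ax.set_xlabel("significant isoacceptors")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
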