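"""Readers/writers for citation-count tables and synthetic fixtures.

Counts travel as plain TSV with the exact header ``article_id\tcitations``;
article identifiers are opaque strings and row order is preserved on a
round trip.  The fixture generator produces heavy-tailed pseudo-observed
citation tables (negative-binomial marginals repaired to an exact total)
for fitting experiments when no real citation data is at hand.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .base import CitationCounts, as_counts
from .errors import CountsFormatError, ParameterError

__all__ = [
    "HEADER",
    "read_counts",
    "write_counts",
    "counts_from_table",
    "table_from_counts",
    "generate_fixture",
    "write_trajectory",
    "read_trajectory",
    "load_config",
]

HEADER = "article_id\tcitations"


def read_counts(path) -> pd.DataFrame:
    """Read a citation-counts TSV into a DataFrame (article_id, citations).

    Malformed files are rejected, not coerced: the header must match
    exactly, citations must be nonnegative integers, and article ids
    must be unique.  Errors name the offending line (1-based).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != HEADER:
        raise CountsFormatError(
            f"expected header {HEADER!r}, got {lines[0]!r}" if lines else "empty file",
            line=1,
        )
    ids: list[str] = []
    cits: list[int] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        if raw == "":
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise CountsFormatError(f"expected 2 tab-separated fields, got {len(parts)}", line=lineno)
        art, cit = parts
        if art == "":
            raise CountsFormatError("empty article_id", line=lineno)
        if art in seen:
            raise CountsFormatError(f"duplicate article_id {art!r}", line=lineno)
        try:
            value = int(cit)
        except ValueError:
            raise CountsFormatError(f"non-integer citation count {cit!r}", line=lineno) from None
        if value < 0:
            raise CountsFormatError(f"negative citation count {value}", line=lineno)
        seen.add(art)
        ids.append(art)
        cits.append(value)
    if not ids:
        raise CountsFormatError("no data rows")
    return pd.DataFrame({"article_id": ids, "citations": np.asarray(cits, dtype=np.int64)})


def write_counts(table, path) -> None:
    """Write a counts table (DataFrame, CitationCounts or array) as TSV."""
    frame = table if isinstance(table, pd.DataFrame) else table_from_counts(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER + "\n")
        for art, cit in zip(frame["article_id"], frame["citations"]):
            fh.write(f"{art}\t{int(cit)}\n")


def counts_from_table(frame: pd.DataFrame) -> CitationCounts:
    """Extract the count vector from a counts DataFrame."""
    return CitationCounts(np.asarray(frame["citations"], dtype=np.int64))


def table_from_counts(counts, ids=None) -> pd.DataFrame:
    """Build a counts DataFrame, generating ``artNNNNN`` ids if absent."""
    c = as_counts(counts)
    if ids is None:
        width = max(len(str(c.R - 1)), 5)
        ids = [f"art{i:0{width}d}" for i in range(c.R)]
    if len(ids) != c.R:
        raise ParameterError("ids length must match the number of articles")
    return pd.DataFrame({"article_id": list(ids), "citations": c.counts})


def generate_fixture(R: int, C: int, dispersion: float, seed: int) -> pd.DataFrame:
    """Synthetic heavy-tailed citation table with an exact total.

    Draws R negative-binomial counts with mean C/R and shape
    ``dispersion`` (small values give heavier tails: variance is
    mu + mu^2/dispersion), then repairs the vector to sum exactly to C
    by uniformly random unit increments or decrements (decrements only
    on positive entries).  This emulates the strong positive skew of
    real citation distributions — very few highly cited articles and
    many poorly cited ones — and serves as a stand-in for observed data
    in fitting demonstrations.
    """
    if int(R) != R or R < 1:
        raise ParameterError("R must be a positive integer")
    if int(C) != C or C < 0:
        raise ParameterError("C must be a nonnegative integer")
    if not dispersion > 0:
        raise ParameterError("dispersion must be positive")
    R, C = int(R), int(C)
    rng = np.random.default_rng(seed)
    if C == 0:
        counts = np.zeros(R, dtype=np.int64)
        return table_from_counts(CitationCounts(counts))
    mu = C / R
    p = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p, size=R).astype(np.int64)
    deficit = C - int(counts.sum())
    while deficit > 0:
        idx = rng.integers(R, size=deficit)
        np.add.at(counts, idx, 1)
        deficit = C - int(counts.sum())
    while deficit < 0:
        positive = np.nonzero(counts > 0)[0]
        take = min(-deficit, positive.size)
        idx = rng.choice(positive, size=take, replace=False)
        counts[idx] -= 1
        deficit = C - int(counts.sum())
    return table_from_counts(CitationCounts(counts))


def write_trajectory(trajectory, path, ids=None) -> None:
    """Write a trajectory as long TSV: epoch, article_id, probability."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    R = trajectory.R
    if ids is None:
        width = max(len(str(R - 1)), 5)
        ids = [f"art{i:0{width}d}" for i in range(R)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch\tarticle_id\tprobability\n")
        for k, epoch in enumerate(trajectory.epochs):
            row = trajectory.probabilities[k]
            for i in range(R):
                fh.write(f"{int(epoch)}\t{ids[i]}\t{row[i]:.10g}\n")


def read_trajectory(path):
    """Read a long-format trajectory TSV back into a Trajectory."""
    from .base import Trajectory

    frame = pd.read_csv(path, sep="\t")
    expected = ["epoch", "article_id", "probability"]
    if list(frame.columns) != expected:
        raise CountsFormatError(f"expected columns {expected}, got {list(frame.columns)}")
    wide = frame.pivot(index="epoch", columns="article_id", values="probability")
    wide = wide.sort_index()
    # preserve first-appearance article order, not alphabetical
    order = list(dict.fromkeys(frame["article_id"]))
    wide = wide[order]
    return Trajectory(epochs=wide.index.to_numpy(), probabilities=wide.to_numpy())


def load_config(path) -> dict:
    """Load a YAML run-configuration mapping (flag name -> value)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParameterError("config file must contain a mapping")
    return cfg
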