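"""Knockdown-signature store: matrices of differential-expression scores for
gene perturbations, with metadata filtering, top/bottom gene-set extraction
and GMT / GCTX / long-TSV I/O.

The store mirrors the LINCS Level-5 layout: a genes x signatures matrix of
moderated z-like scores, signature metadata (sig_id, pert_type, pert_gene,
cell, time) and an optional gene-info table translating numeric gene ids to
symbols. Consensus shRNA knockdown signatures carry pert_type
``trt_sh.cgs``. GCTX access reads only the requested columns, so a store far
larger than memory can be subset cheaply.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignatureIdError",
    "GeneSetCollection",
    "SignatureStore",
    "filter_consensus_shrna",
    "extract_top_bottom_sets",
    "parse_signature_id",
    "read_gmt",
    "write_gmt",
    "read_gctx",
    "write_gctx",
    "read_gctx_column_ids",
]

CONSENSUS_SHRNA = "trt_sh.cgs"


class SignatureIdError(ValueError):
    """A signature id does not follow the CGS<d>_<CELL>_<GENE>:<suffix> grammar."""

    def __init__(self, sig_id: str):
        self.sig_id = sig_id
        super().__init__(f"cannot parse signature id: {sig_id!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets; members unique within a set, insertion-ordered."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def add(self, name: str, members: list[str]) -> None:
        seen: dict[str, None] = dict.fromkeys(members)
        self.sets[name] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


def filter_consensus_shrna(meta: pd.DataFrame, time_filter: str | None = "96H") -> list[str]:
    """sig_ids with pert_type trt_sh.cgs and, if given, a matching time label.

    The time label matches the metadata ``time`` column when present, else a
    substring of the sig_id (the convention of the public store). Empty result
    warns and returns [].
    """
    sel = meta[meta["pert_type"] == CONSENSUS_SHRNA]
    if time_filter is not None:
        if "time" in sel.columns:
            sel = sel[sel["time"] == time_filter]
        else:
            sel = sel[sel["sig_id"].str.contains(re.escape(time_filter))]
    ids = sel["sig_id"].tolist()
    if not ids:
        warnings.warn("no consensus shRNA signatures match the filter", stacklevel=2)
    return ids


def extract_top_bottom_sets(
    scores: pd.Series,
    k: int = 20,
    symbols: pd.Series | None = None,
) -> tuple[list[str], list[str]]:
    """(up, down) gene sets from one signature's score vector.

    ``up`` holds the k genes with the highest scores, ``down`` the k lowest;
    ties at the boundary break by ascending gene id, which makes the selection
    deterministic and makes extraction on a negated signature swap the two
    sets exactly. *symbols* (gene id -> symbol) translates ids after
    selection.
    """
    s = scores[np.isfinite(scores.to_numpy(dtype=float))]
    if len(s) < 2 * k:
        raise ValueError(f"signature has {len(s)} finite scores; need >= {2 * k} for k={k}")
    frame = pd.DataFrame({"gene_id": s.index, "score": s.to_numpy(dtype=float)})
    up_order = frame.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    down_order = frame.sort_values(["score", "gene_id"], ascending=[True, True], kind="mergesort")
    up = up_order["gene_id"].head(k).tolist()
    down = down_order["gene_id"].head(k).tolist()
    if symbols is not None:
        up = [symbols.get(g, str(g)) for g in up]
        down = [symbols.get(g, str(g)) for g in down]
    return up, down


_SIG_ID = re.compile(
    r"^CGS\d+_(?P<cell>[A-Za-z0-9]+)_(?:\d+\s?H:)?(?P<gene>[A-Za-z0-9.\-]+)(?::[^\s]*)?$"
)


def parse_signature_id(sig_id: str) -> tuple[str, str]:
    """(cell, perturbed gene) from a consensus-signature id.

    Grammar: ``CGS<digits>_<CELL>_<GENE>[:<suffix>]`` with an optional
    embedded ``<time>:`` token before the gene (as in the public store's
    ids). Raises :class:`SignatureIdError` on anything else.
    """
    m = _SIG_ID.match(sig_id)
    if m is None:
        raise SignatureIdError(sig_id)
    return m.group("cell"), m.group("gene")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    out = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} ({len(fields)} fields)")
            out.add(fields[0], fields[2:])
    return out


# ---------------------------------------------------------------------------
# GCTX (HDF5): matrix stored as (n_signatures, n_genes) at 0/DATA/0/matrix
# with ids at 0/META/ROW/id (genes) and 0/META/COL/id (signatures), matching
# the public LINCS layout. Column subsets are read without touching the rest.
# ---------------------------------------------------------------------------

_MATRIX = "0/DATA/0/matrix"
_ROW_ID = "0/META/ROW/id"
_COL_ID = "0/META/COL/id"


def write_gctx(matrix: pd.DataFrame, path) -> None:
    """Write a genes x signatures frame; deterministic bytes at fixed input."""
    import h5py

    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset(_MATRIX, data=matrix.to_numpy(dtype=np.float32).T, track_times=False)
        f.create_dataset(_ROW_ID, data=np.array([str(i) for i in matrix.index], dtype="S"), track_times=False)
        f.create_dataset(_COL_ID, data=np.array([str(c) for c in matrix.columns], dtype="S"), track_times=False)


def read_gctx_column_ids(path) -> list[str]:
    import h5py

    with h5py.File(path, "r") as f:
        return [c.decode() for c in f[_COL_ID][()]]


def read_gctx(path, cids: list[str] | None = None) -> pd.DataFrame:
    """Genes x signatures frame; *cids* restricts to those signature columns,
    reading only the matching rows of the on-disk matrix."""
    import h5py

    with h5py.File(path, "r") as f:
        cols = [c.decode() for c in f[_COL_ID][()]]
        rows = [r.decode() for r in f[_ROW_ID][()]]
        if cids is None:
            data = f[_MATRIX][()]
            keep = cols
        else:
            pos = {c: i for i, c in enumerate(cols)}
            missing = [c for c in cids if c not in pos]
            if missing:
                raise KeyError(f"signature id(s) not in store: {missing[:5]}")
            idx = sorted(pos[c] for c in cids)
            data = f[_MATRIX][idx, :]
            keep = [cols[i] for i in idx]
    frame = pd.DataFrame(data.T.astype(np.float64), index=rows, columns=keep)
    if cids is not None:
        frame = frame[cids]
    return frame


class SignatureStore:
    """Signature matrix + metadata + optional gene-id -> symbol table."""

    def __init__(self, matrix: pd.DataFrame, meta: pd.DataFrame, gene_info: pd.Series | None = None):
        missing_meta = set(matrix.columns) - set(meta["sig_id"])
        if missing_meta:
            raise ValueError(f"signatures without metadata: {sorted(missing_meta)[:5]}")
        dup = matrix.index.duplicated()
        if dup.any():
            raise ValueError("duplicate gene ids in signature matrix")
        self.matrix = matrix
        self.meta = meta.reset_index(drop=True)
        self.gene_info = gene_info

    @classmethod
    def from_long_tsv(cls, scores_path, meta_path, gene_info: pd.Series | None = None) -> "SignatureStore":
        """Long-format fixture backend: columns gene_id, sig_id, score."""
        long = pd.read_csv(scores_path, sep="\t", dtype={"gene_id": str, "sig_id": str})
        if long.duplicated(["gene_id", "sig_id"]).any():
            raise ValueError("duplicate (gene_id, sig_id) entries")
        matrix = long.pivot(index="gene_id", columns="sig_id", values="score")
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        return cls(matrix, meta, gene_info)

    @classmethod
    def from_gctx(cls, gctx_path, meta_path, gene_info: pd.Series | None = None, cids: list[str] | None = None) -> "SignatureStore":
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if cids is None:
            cids = filter_consensus_shrna(meta, time_filter=None) or None
        matrix = read_gctx(gctx_path, cids=cids)
        meta = meta[meta["sig_id"].isin(matrix.columns)]
        return cls(matrix, meta, gene_info)

    def consensus_shrna_ids(self, time_filter: str | None = "96H") -> list[str]:
        return [s for s in filter_consensus_shrna(self.meta, time_filter) if s in self.matrix.columns]

    def scores(self, sig_id: str) -> pd.Series:
        return self.matrix[sig_id]

    def extract_collections(self, sig_ids: list[str], k: int = 20) -> tuple[GeneSetCollection, GeneSetCollection]:
        """Up/down GeneSetCollections (one set per signature, named by sig_id)."""
        up_coll, down_coll = GeneSetCollection(), GeneSetCollection()
        for sid in sig_ids:
            up, down = extract_top_bottom_sets(self.scores(sid), k=k, symbols=self.gene_info)
            up_coll.add(sid, up)
            down_coll.add(sid, down)
        return up_coll, down_coll
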