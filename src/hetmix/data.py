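"""Dataset ingestion, internal encoding, synthetic sampling and output.

A :class:`DataSet` holds an N×p matrix in encoded form: discrete features as
alphabet indices, continuous features as raw floats, missing entries as NaN.
Per-feature domain metadata records each feature's type and (for discrete
features) its ordered alphabet, so encoded matrices decode back to symbols
losslessly.

FASTA ingestion follows the fixed-length convention for positional sequence
models: every sequence position becomes one discrete feature, so N aligned
sequences of length L yield an N×L discrete dataset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distributions import DomainError

__all__ = [
    "FeatureDomain",
    "DataSet",
    "ClusterAssignment",
    "read_fasta",
    "write_fasta",
    "read_table",
    "sample_dataset",
    "write_clustering",
    "read_clustering",
    "DNA_ALPHABET",
    "PROTEIN_ALPHABET",
]

DNA_ALPHABET = tuple("ACGT")
PROTEIN_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class FeatureDomain:
    """Type metadata for one feature: 'discrete' (with alphabet) or 'continuous'."""

    kind: str  # "discrete" | "continuous"
    alphabet: tuple[str, ...] | None = None
    name: str | None = None

    def __post_init__(self):
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "discrete":
            if not self.alphabet:
                raise ValueError("discrete feature needs an alphabet")
            if len(set(self.alphabet)) != len(self.alphabet):
                raise ValueError("alphabet symbols must be unique")


class DataSet:
    """N×p table of mixed-type observations with missing-value support."""

    def __init__(self, ids: Sequence[str], X: np.ndarray,
                 domains: Sequence[FeatureDomain], missing_marker: str = "?"):
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if X.shape[0] != len(ids):
            raise ValueError("ids / row count mismatch")
        if X.shape[1] != len(domains):
            raise ValueError("domains / column count mismatch")
        for j, dom in enumerate(domains):
            if dom.kind == "discrete":
                col = X[:, j]
                codes = col[~np.isnan(col)]
                if codes.size and (codes.min() < 0
                                   or codes.max() >= len(dom.alphabet)):
                    raise ValueError(f"feature {j}: code out of alphabet range")
        self.ids = ids
        self.X = X
        self.domains = list(domains)
        self.missing_marker = missing_marker

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def __repr__(self):
        kinds = "".join("d" if d.kind == "discrete" else "c" for d in self.domains)
        return f"DataSet(n={self.n}, p={self.p}, features={kinds})"

    # -- raw-value interface ------------------------------------------------
    @classmethod
    def from_rows(cls, ids: Sequence[str], rows: Sequence[Sequence],
                  domains: Sequence[FeatureDomain],
                  missing_marker: str = "?") -> "DataSet":
        """Build a dataset from raw symbol/number rows, encoding on the way in."""
        X = np.empty((len(rows), len(domains)), dtype=float)
        for i, row in enumerate(rows):
            if len(row) != len(domains):
                raise ValueError(
                    f"row {i} has {len(row)} entries, expected {len(domains)}")
            X[i] = _encode_row(row, domains, missing_marker)
        return cls(ids, X, domains, missing_marker)

    def encode_row(self, row: Sequence) -> np.ndarray:
        return _encode_row(row, self.domains, self.missing_marker)

    def decode_row(self, i: int) -> list:
        out = []
        for j, dom in enumerate(self.domains):
            v = self.X[i, j]
            if np.isnan(v):
                out.append(self.missing_marker)
            elif dom.kind == "discrete":
                out.append(dom.alphabet[int(v)])
            else:
                out.append(float(v))
        return out

    def sequences(self) -> list[str]:
        """Decode all-discrete single-character rows back to sequence strings."""
        if any(d.kind != "discrete" for d in self.domains):
            raise ValueError("sequences() requires an all-discrete dataset")
        return ["".join(str(v) for v in self.decode_row(i)) for i in range(self.n)]


def _encode_row(row, domains, missing_marker) -> np.ndarray:
    out = np.empty(len(domains))
    for j, (v, dom) in enumerate(zip(row, domains)):
        if v is None or (isinstance(v, str) and v == missing_marker) or (
                isinstance(v, float) and np.isnan(v)):
            out[j] = np.nan
        elif dom.kind == "discrete":
            sym = str(v)
            try:
                out[j] = dom.alphabet.index(sym)
            except ValueError:
                raise DomainError(
                    f"symbol {sym!r} not in alphabet of feature {j}"
                    f" ({''.join(dom.alphabet)})") from None
        else:
            out[j] = float(v)
    return out


# ---------------------------------------------------------------------------
# FASTA

def _infer_alphabet(symbols: set[str]) -> tuple[str, ...]:
    if symbols <= set(DNA_ALPHABET):
        return DNA_ALPHABET
    if symbols <= set(PROTEIN_ALPHABET):
        return PROTEIN_ALPHABET
    return tuple(sorted(symbols))


def read_fasta(path, alphabet: str | Sequence[str] | None = None,
               missing_symbols: Sequence[str] = ("-", ".")) -> DataSet:
    """Read fixed-length sequences; each position becomes one discrete feature.

    Parameters
    ----------
    alphabet
        ``None`` (autodetect DNA → protein → observed symbols), ``"dna"``,
        ``"protein"``, or an explicit symbol list.  With an explicit or named
        alphabet, out-of-alphabet symbols raise :class:`DomainError`.
    missing_symbols
        Characters treated as the missing-value sentinel (gap characters).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        offending = [i for i, s in zip(ids, seqs) if len(s) != len(seqs[0])]
        raise ValueError(
            f"sequences must share one length; mismatched ids: {offending}")
    missing = set(missing_symbols)
    observed = set("".join(seqs)) - missing
    if alphabet is None:
        alpha = _infer_alphabet(observed)
    elif alphabet == "dna":
        alpha = DNA_ALPHABET
    elif alphabet == "protein":
        alpha = PROTEIN_ALPHABET
    else:
        alpha = tuple(str(s).upper() for s in alphabet)
    bad = observed - set(alpha)
    if bad:
        raise DomainError(
            f"symbols {sorted(bad)} not in alphabet {''.join(alpha)}")
    p = lengths.pop()
    domains = [FeatureDomain("discrete", alpha, name=f"pos{j}") for j in range(p)]
    marker = next(iter(missing_symbols), "-")
    rows = [[marker if c in missing else c for c in s] for s in seqs]
    return DataSet.from_rows(ids, rows, domains, missing_marker=marker)


def write_fasta(dataset: DataSet, path) -> None:
    """Write an all-discrete dataset as FASTA (inverse of :func:`read_fasta`)."""
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(dataset.ids, dataset.sequences())]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# delimited tables

def read_table(path, schema: Sequence[str] | dict[str, str] | None = None,
               missing_marker: str = "?", sep: str | None = None) -> DataSet:
    """Read a delimited table (header row required; first column = sample id).

    ``schema`` gives per-column types: a list/dict of ``"discrete"``/
    ``"continuous"`` (abbreviations ``"d"``/``"c"`` accepted). ``None``
    infers: columns that parse fully as numbers are continuous, the rest
    discrete with the observed symbols as alphabet.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("table needs an id column plus at least one feature")
    ids = df.iloc[:, 0].tolist()
    feats = df.columns[1:].tolist()
    if isinstance(schema, dict):
        schema = [schema[c] for c in feats]
    if schema is not None and len(schema) != len(feats):
        raise ValueError("schema length must match feature column count")

    domains, cols = [], []
    for jj, name in enumerate(feats):
        raw = df[name].tolist()
        present = [v for v in raw if v != missing_marker]
        if schema is None:
            kind = "continuous" if _all_numeric(present) else "discrete"
        else:
            s = schema[jj].lower()
            kind = {"d": "discrete", "discrete": "discrete",
                    "c": "continuous", "continuous": "continuous"}.get(s)
            if kind is None:
                raise ValueError(f"unknown schema entry {schema[jj]!r}")
        if kind == "continuous":
            col = np.empty(len(raw))
            for i, v in enumerate(raw):
                if v == missing_marker:
                    col[i] = np.nan
                else:
                    try:
                        col[i] = float(v)
                    except ValueError:
                        raise ValueError(
                            f"cannot parse cell at row {i}, column {name!r}: "
                            f"{v!r}") from None
            domains.append(FeatureDomain("continuous", name=name))
        else:
            alpha = tuple(sorted(set(present)))
            if not alpha:
                raise ValueError(f"column {name!r} is entirely missing")
            index = {s: k for k, s in enumerate(alpha)}
            col = np.array([np.nan if v == missing_marker else index[v]
                            for v in raw], dtype=float)
            domains.append(FeatureDomain("discrete", alpha, name=name))
        cols.append(col)
    return DataSet(ids, np.column_stack(cols), domains, missing_marker)


def _all_numeric(values) -> bool:
    if not values:
        return False
    for v in values:
        try:
            float(v)
        except ValueError:
            return False
    return True


# ---------------------------------------------------------------------------
# synthetic sampling

def sample_dataset(model, n: int, seed=None,
                   id_prefix: str = "s") -> tuple[DataSet, np.ndarray]:
    """Draw ``n`` samples from a mixture model: component per sample from π,
    then features from that component. Returns the dataset and the generating
    component labels."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    labels = rng.choice(model.K, size=n, p=model.pi)
    X = np.empty((n, model.p))
    for k in range(model.K):
        idx = np.flatnonzero(labels == k)
        if idx.size:
            X[idx] = model.sample_component_rows(k, rng, idx.size)
    ids = [f"{id_prefix}{i}" for i in range(n)]
    return DataSet(ids, X, model.feature_domains(), "?"), labels


# ---------------------------------------------------------------------------
# clustering output

@dataclass
class ClusterAssignment:
    """Cluster labels (−1 = unassigned) plus the full membership posterior."""

    labels: np.ndarray
    posterior: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.labels.shape[0] != self.posterior.shape[0]:
            raise ValueError("labels / posterior length mismatch")
        rowsums = self.posterior.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError("posterior rows must sum to 1")

    @property
    def k(self) -> int:
        return self.posterior.shape[1]

    def cluster_members(self, ids: Sequence[str]) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lab in sorted(set(self.labels.tolist())):
            out[lab] = [i for i, l in zip(ids, self.labels) if l == lab]
        return out


def write_clustering(assignment: ClusterAssignment, dataset: DataSet, path) -> None:
    """Write id, label (NA if unassigned) and per-component posterior as TSV."""
    if len(dataset.ids) != assignment.labels.shape[0]:
        raise ValueError("assignment does not match dataset size")
    header = ["id", "label"] + [f"p{k}" for k in range(assignment.k)]
    buf = io.StringIO()
    buf.write("\t".join(header) + "\n")
    for i, sid in enumerate(dataset.ids):
        lab = assignment.labels[i]
        fields = [sid, "NA" if lab < 0 else str(lab)]
        fields += [f"{v:.10g}" for v in assignment.posterior[i]]
        buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue())


def read_clustering(path) -> ClusterAssignment:
    df = pd.read_csv(path, sep="\t", dtype={"label": str},
                     keep_default_na=False)
    labels = np.array([-1 if l == "NA" else int(l) for l in df["label"]])
    pcols = [c for c in df.columns if c.startswith("p")]
    return ClusterAssignment(labels, df[pcols].to_numpy(float))
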