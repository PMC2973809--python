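"""File formats: tidy pair tables, moment tables, run configuration.

Pairwise FISH data are inherently ragged -- each gene pair has its own
number of observed cells (real data sets range over two orders of
magnitude) -- so the on-disk format is a long/tidy TSV with one row per
cell: ``cell_id  gene_a  gene_b  count_a  count_b``, preceded by ``#``
header lines carrying the regime tag and seed.  Simulation outputs can carry
a JSON sidecar with the true generating model so recovery experiments are a
one-command round trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .binarize import MomentEstimates
from .models import Model, model_to_dict
from .simulate import PairObservationSet

__all__ = [
    "RunConfig",
    "write_pair_table",
    "read_pair_table",
    "write_moments",
    "read_moments",
    "sidecar_path",
]

COLUMNS = ("cell_id", "gene_a", "gene_b", "count_a", "count_b")


@dataclass
class RunConfig:
    """Serializable settings that, with the input files, reproduce a run."""

    seed: int = 0
    regime: str = "bursty_binary"
    n_restarts: int = 10
    n_quad: int = 128
    threshold_policy: str = "median"
    output_dir: str = "."
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".model.json")


def write_pair_table(data: PairObservationSet, path,
                     true_model: Model | None = None) -> None:
    """Write a tidy TSV pair table (plus optional true-model sidecar)."""
    path = Path(path)
    lines = [f"# fishdyn pair table v1",
             f"# regime: {data.regime}",
             f"# seed: {data.seed if data.seed is not None else 'none'}",
             "\t".join(COLUMNS)]
    cell = 0
    integral = data.regime != "continuous"
    for (i, j), c in zip(data.pairs, data.counts):
        ga, gb = data.gene_names[i], data.gene_names[j]
        for a, b in c:
            # repr of a Python float is the shortest string that round-trips
            va, vb = (f"{a:.0f}", f"{b:.0f}") if integral \
                else (repr(float(a)), repr(float(b)))
            lines.append(f"c{cell}\t{ga}\t{gb}\t{va}\t{vb}")
            cell += 1
    path.write_text("\n".join(lines) + "\n")
    if true_model is not None:
        sidecar_path(path).write_text(
            json.dumps(model_to_dict(true_model), indent=1) + "\n")


def read_pair_table(path) -> PairObservationSet:
    """Read a tidy TSV pair table; malformed rows are reported by line.

    Genes are indexed in first-appearance order; all rows sharing a gene
    pair are collected into one observation block.
    """
    path = Path(path)
    regime = None
    seed = None
    header = None
    genes: dict[str, int] = {}
    blocks: dict[tuple[int, int], list[tuple[float, float]]] = {}
    order: list[tuple[int, int]] = []
    any_fractional = False
    binary_only = True

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("regime:"):
                    regime = body.split(":", 1)[1].strip()
                elif body.startswith("seed:"):
                    tok = body.split(":", 1)[1].strip()
                    seed = None if tok == "none" else int(tok)
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in COLUMNS if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}: line {lineno}: missing column(s) "
                        f"{', '.join(missing)}")
                idx = {c: header.index(c) for c in COLUMNS}
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            ga, gb = fields[idx["gene_a"]], fields[idx["gene_b"]]
            try:
                a = float(fields[idx["count_a"]])
                b = float(fields[idx["count_b"]])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric count") from None
            if a < 0 or b < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            if ga == gb:
                raise ValueError(
                    f"{path}: line {lineno}: pair probes gene {ga!r} twice")
            for g in (ga, gb):
                genes.setdefault(g, len(genes))
            key = (genes[ga], genes[gb])
            if key not in blocks:
                blocks[key] = []
                order.append(key)
            blocks[key].append((a, b))
            if a != int(a) or b != int(b):
                any_fractional = True
            if a not in (0.0, 1.0) or b not in (0.0, 1.0):
                binary_only = False

    if header is None or not blocks:
        raise ValueError(f"{path}: no data rows found")
    if regime is None:
        regime = ("continuous" if any_fractional
                  else "bursty_binary" if binary_only else "bursty_count")
    return PairObservationSet(
        gene_names=list(genes), pairs=order,
        counts=[np.asarray(blocks[k], dtype=float) for k in order],
        regime=regime, seed=seed)


# ---------------------------------------------------------------------------
# moment tables
# ---------------------------------------------------------------------------

def write_moments(est: MomentEstimates, prefix) -> tuple[Path, Path]:
    """Write pair-level and gene-level moment tables as TSV."""
    prefix = Path(prefix)
    pair_path = prefix.with_name(prefix.name + ".pairs.tsv")
    gene_path = prefix.with_name(prefix.name + ".genes.tsv")
    lines = ["gene_a\tgene_b\tM\tc_hat\tc_var\tvar_floored"]
    for (i, j) in est.observed_pairs():
        lines.append(
            f"{est.gene_names[i]}\t{est.gene_names[j]}\t"
            f"{est.n_obs_pair[i, j]}\t{est.c_hat[i, j]:.10g}\t"
            f"{est.c_var[i, j]:.10g}\t{int(est.var_floored[i, j])}")
    pair_path.write_text("\n".join(lines) + "\n")
    lines = ["gene\tn_obs\tp_hat\tthreshold"]
    for g, name in enumerate(est.gene_names):
        lines.append(f"{name}\t{est.n_obs_gene[g]}\t{est.p_hat[g]:.10g}\t"
                     f"{est.thresholds[g]:g}")
    gene_path.write_text("\n".join(lines) + "\n")
    return pair_path, gene_path


def read_moments(prefix) -> MomentEstimates:
    prefix = Path(prefix)
    pair_path = prefix.with_name(prefix.name + ".pairs.tsv")
    gene_path = prefix.with_name(prefix.name + ".genes.tsv")
    gene_rows = [ln.split("\t") for ln in
                 gene_path.read_text().strip().split("\n")[1:]]
    names = [r[0] for r in gene_rows]
    n = len(names)
    idx = {g: k for k, g in enumerate(names)}
    p_hat = np.array([float(r[2]) for r in gene_rows])
    n_obs_gene = np.array([int(r[1]) for r in gene_rows])
    thresholds = np.array([float(r[3]) for r in gene_rows])
    c_hat = np.full((n, n), np.nan)
    c_var = np.full((n, n), np.nan)
    M = np.zeros((n, n), dtype=int)
    floored = np.zeros((n, n), dtype=bool)
    for r in [ln.split("\t") for ln in
              pair_path.read_text().strip().split("\n")[1:]]:
        i, j = idx[r[0]], idx[r[1]]
        M[i, j] = M[j, i] = int(r[2])
        c_hat[i, j] = c_hat[j, i] = float(r[3])
        c_var[i, j] = c_var[j, i] = float(r[4])
        floored[i, j] = floored[j, i] = bool(int(r[5]))
    return MomentEstimates(gene_names=names, p_hat=p_hat, c_hat=c_hat,
                           c_var=c_var, n_obs_pair=M, n_obs_gene=n_obs_gene,
                           thresholds=thresholds, var_floored=floored)


def read_published_counts(path) -> PairObservationSet:
    """Loader stub for externally published pairwise FISH tables.

    Expects the same tidy TSV shape as :func:`read_pair_table` (one row per
    cell: cell_id, gene_a, gene_b, count_a, count_b) with integer counts; no
    data ships with the package.
    """
    data = read_pair_table(path)
    if data.regime == "continuous":
        raise ValueError("expected integer mRNA counts")
    return data
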