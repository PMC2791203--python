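"""Readers and writers for all external formats.

Formats consumed: probe tables (TSV: ``chrom  pos  <sample...>``), arm and
gene annotations (BED, 0-based half-open, name column carrying the arm or
gene identifier), gene-gene interaction tables (TSV with confidence), and
plain-text gene-category lists.  Formats produced: peak lists (TSV with
full metadata and BEDPE intervals of peak +/- sigma), networks (GraphML
with node/edge attributes, SIF with topology only) and interpolated grids
(compressed npz).

Float columns are written with a fixed ``repr``-faithful format so repeated
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from cooccur.annotate import GeneRecord, InteractionTable
from cooccur.grid import ArmDefinition, GridMatrix, ProbeTrack
from cooccur.peaks import Peak, RankedPeakList

FLOAT_FMT = "%.17g"  # full round-trip precision, still byte-deterministic


# ---------------------------------------------------------------- probe table

def read_probe_table(path: str | Path, one_based: bool = False) -> list[ProbeTrack]:
    """Read a probe table TSV into one :class:`ProbeTrack` per sample column.

    Positions are sorted within each chromosome; malformed numeric cells and
    duplicate (chrom, pos) rows are reported with 1-based line numbers.
    Set ``one_based=True`` for tables with 1-based positions; internal
    coordinates are 0-based.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, float_precision="round_trip")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValueError(
            f"{path}: expected header 'chrom\\tpos\\t<sample...>', got {list(df.columns)}"
        )
    for col in df.columns[1:]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = converted
    df["pos"] = df["pos"].astype(np.int64)
    if one_based:
        df["pos"] -= 1
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValueError(f"{path}: duplicate (chrom, pos) at line {line}")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return [
        ProbeTrack(
            sample_id=col,
            chromosomes=df["chrom"].to_numpy(dtype=object),
            positions=df["pos"].to_numpy(),
            values=df[col].to_numpy(dtype=float),
        )
        for col in df.columns[2:]
    ]


def write_probe_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def probe_tracks_from_table(table: pd.DataFrame) -> list[ProbeTrack]:
    """In-memory equivalent of :func:`read_probe_table` for a DataFrame."""
    df = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return [
        ProbeTrack(
            sample_id=col,
            chromosomes=df["chrom"].astype(str).to_numpy(dtype=object),
            positions=df["pos"].to_numpy(),
            values=df[col].to_numpy(dtype=float),
        )
        for col in df.columns[2:]
    ]


# ----------------------------------------------------------------------- BED

def read_arms_bed(path: str | Path) -> list[ArmDefinition]:
    """Arm definitions from BED with name column ``<chrom>_<p|q>``."""
    arms = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{i}: arm BED needs 4 columns (chrom start end name)")
        chrom, start, end, name = fields[:4]
        if "_" not in name:
            raise ValueError(f"{path}:{i}: arm name {name!r} must end in _p or _q")
        arm = name.rsplit("_", 1)[1]
        arms.append(ArmDefinition(chromosome=chrom, arm=arm, start=int(start), end=int(end)))
    return arms


def write_arms_bed(arms: list[ArmDefinition], path: str | Path) -> None:
    lines = [f"{a.chromosome}\t{a.start}\t{a.end}\t{a.name}" for a in arms]
    Path(path).write_text("\n".join(lines) + "\n")


def read_genes_bed(path: str | Path) -> list[GeneRecord]:
    """Gene records from BED with the gene identifier in the name column."""
    genes = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{i}: gene BED needs 4 columns (chrom start end name)")
        chrom, start, end, name = fields[:4]
        genes.append(GeneRecord(gene_id=name, chromosome=chrom, start=int(start), end=int(end)))
    return genes


def write_genes_bed(genes: list[GeneRecord], path: str | Path) -> None:
    lines = [f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}" for g in genes]
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------- interactions & categories

def read_interactions(path: str | Path) -> InteractionTable:
    """TSV ``gene_a  gene_b  confidence`` (header optional)."""
    table = InteractionTable()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: expected 'gene_a\\tgene_b\\tconfidence'")
        if i == 1 and fields[2].lower() in ("confidence", "score"):
            continue
        try:
            conf = float(fields[2])
        except ValueError:
            raise ValueError(f"{path}:{i}: non-numeric confidence {fields[2]!r}") from None
        table.add(fields[0], fields[1], conf)
    return table


def read_gene_list(path: str | Path) -> set[str]:
    """Plain text, one gene per line; blank lines and comments skipped."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


# ----------------------------------------------------------------- peak lists

PEAK_COLUMNS = [
    "rank", "score", "mode", "scale_bp",
    "chrom_a", "arm_a", "pos_a", "chrom_b", "arm_b", "pos_b",
]


def write_peaks_tsv(peaks: RankedPeakList | list[Peak], path: str | Path) -> None:
    rows = [
        {
            "rank": p.rank if p.rank is not None else "",
            "score": p.score,
            "mode": p.mode,
            "scale_bp": int(p.scale_bp),
            "chrom_a": p.chrom_a, "arm_a": p.arm_a, "pos_a": p.pos_a,
            "chrom_b": p.chrom_b, "arm_b": p.arm_b, "pos_b": p.pos_b,
        }
        for p in peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_peaks_tsv(path: str | Path) -> list[Peak]:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom_a": str, "chrom_b": str},
        float_precision="round_trip",
    )
    return [
        Peak(
            chrom_a=str(r.chrom_a), arm_a=r.arm_a, pos_a=int(r.pos_a),
            chrom_b=str(r.chrom_b), arm_b=r.arm_b, pos_b=int(r.pos_b),
            score=float(r.score), mode=r.mode, scale_bp=float(r.scale_bp),
            rank=None if pd.isna(r.rank) else int(r.rank),
        )
        for r in df.itertuples()
    ]


def write_peaks_bedpe(peaks: RankedPeakList | list[Peak], path: str | Path) -> None:
    """BEDPE with each locus as the peak +/- sigma interval.

    ``name`` is ``mode/scale/rank``; ``score`` the smoothed co-occurrence
    score.  Interval starts are clipped at 0.
    """
    lines = []
    for p in peaks:
        sigma = int(round(p.scale_bp / 6.0))
        name = f"{p.mode}/{int(p.scale_bp)}/{p.rank if p.rank is not None else '.'}"
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    p.chrom_a, max(0, p.pos_a - sigma), p.pos_a + sigma,
                    p.chrom_b, max(0, p.pos_b - sigma), p.pos_b + sigma,
                    name, FLOAT_FMT % p.score, ".", ".",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ------------------------------------------------------------------- networks

def _stringify(value):
    if isinstance(value, (list, tuple)):
        return json.dumps([list(v) if isinstance(v, tuple) else v for v in value])
    return value


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a co-occurrence graph as GraphML (lossless attrs) or SIF."""
    path = Path(path)
    if fmt == "graphml":
        out = nx.Graph(**{k: _stringify(v) for k, v in graph.graph.items()})
        for n, attrs in graph.nodes(data=True):
            out.add_node(
                n, **{k: _stringify(v) for k, v in attrs.items() if v is not None}
            )
        for u, v, attrs in graph.edges(data=True):
            out.add_edge(u, v, **{k: _stringify(a) for k, a in attrs.items()})
        nx.write_graphml(out, path)
    elif fmt == "sif":
        lines = [f"{u}\tcooccurs\t{v}" for u, v in graph.edges()]
        lines += [f"{n}" for n in nx.isolates(graph)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    G = nx.read_graphml(path)
    return nx.relabel_nodes(G, {n: int(n) for n in G.nodes})


# ----------------------------------------------------------------- grid dump

def write_grid_matrix(gm: GridMatrix, path: str | Path) -> None:
    """Bit-stable container for an interpolated grid matrix (npz)."""
    np.savez_compressed(
        path,
        sample_ids=np.array(gm.sample_ids, dtype=object),
        values=gm.values,
        mask=gm.mask,
        coords=gm.grid.coords,
        spacing=gm.grid.spacing,
        arm_names=np.array(gm.grid.arm_names, dtype=object),
        arm_chroms=np.array([a.chromosome for a in gm.grid.arms], dtype=object),
        arm_starts=np.array([a.start for a in gm.grid.arms]),
        arm_ends=np.array([a.end for a in gm.grid.arms]),
    )
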