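"""Genotype I/O: biallelic GT-only VCF and the matrix-TSV dialect.

The matrix-TSV dialect is a tab-separated table with a header row of marker
ids, one row per sample (first column the sample id), and cells in
``{0, 1, 2, NA}``.  A sidecar panel TSV (columns id, chrom, pos, ref, alt)
carries the marker coordinates; by default it sits next to the matrix as
``<stem>.panel.tsv``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .markers import Marker, MarkerPanel


class ParseError(ValueError):
    """A genotype file failed to parse under the named format."""


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def default_panel_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".panel.tsv")


def read_genotypes(
    path, format: str = "matrix_tsv", panel_path=None
) -> Tuple[GenotypeMatrix, MarkerPanel]:
    """Read genotypes as dosages; returns the matrix and its marker panel."""
    if format == "matrix_tsv":
        return _read_matrix_tsv(path, panel_path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path, format: str = "matrix_tsv", panel_path=None) -> None:
    if format == "matrix_tsv":
        _write_matrix_tsv(g, path, panel_path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path, panel_path=None) -> Tuple[GenotypeMatrix, MarkerPanel]:
    panel_path = panel_path or default_panel_path(path)
    if not Path(panel_path).exists():
        raise ParseError(f"sidecar panel file not found: {panel_path}")
    panel = MarkerPanel.from_tsv(panel_path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"failed to parse genotype matrix {path}: {exc}") from exc
    if set(df.columns) != set(panel.ids):
        raise ParseError(f"matrix columns do not match panel markers in {path}")
    df = df[list(panel.ids)]
    values = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(values), MISSING, values)
    if not np.array_equal(calls, np.round(calls)):
        raise ParseError(f"non-integer genotype cell in {path}")
    return GenotypeMatrix(tuple(str(s) for s in df.index), panel, calls.astype(np.int8)), panel


def _write_matrix_tsv(g: GenotypeMatrix, path, panel_path=None) -> None:
    panel_path = panel_path or default_panel_path(path)
    values = g.calls.astype(object)
    df = pd.DataFrame(values, index=list(g.sample_ids), columns=list(g.panel.ids))
    df = df.mask(df == MISSING)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
    g.panel.to_tsv(panel_path)


# ---------------------------------------------------------------------------
# VCF (GT field only, biallelic sites)
# ---------------------------------------------------------------------------

def _read_vcf(path) -> Tuple[GenotypeMatrix, MarkerPanel]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"failed to open VCF {path}: {exc}") from exc
    samples = tuple(vcf.samples)
    markers = []
    columns = []
    try:
        for variant in vcf:
            vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
            if len(variant.ALT) != 1:
                raise ParseError(f"multi-allelic VCF record rejected: {vid}")
            try:
                marker = Marker(vid, variant.CHROM, variant.POS, variant.REF, variant.ALT[0])
            except ValueError as exc:
                raise ParseError(f"non-SNP VCF record rejected: {vid} ({exc})") from exc
            dosages = np.full(len(samples), MISSING, dtype=np.int8)
            for s, gt in enumerate(variant.genotypes):
                a, b = gt[0], gt[1]
                if a >= 0 and b >= 0:
                    dosages[s] = a + b
            markers.append(marker)
            columns.append(dosages)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed VCF record in {path}: {exc}") from exc
    finally:
        vcf.close()
    order = sorted(range(len(markers)), key=lambda i: markers[i].locus)
    panel = MarkerPanel(markers[i] for i in order)
    if columns:
        calls = np.stack([columns[i] for i in order], axis=1)
    else:
        calls = np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, panel, calls), panel


def _write_vcf(g: GenotypeMatrix, path) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=piecemeal"]
    for chrom in dict.fromkeys(m.chrom for m in g.panel):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(g.sample_ids)
    lines.append("\t".join(header))
    for j, m in enumerate(g.panel):
        row = [m.chrom, str(m.pos), m.id, m.ref_allele, m.alt_allele, ".", "PASS", ".", "GT"]
        row.extend(_GT_STRINGS[int(c)] for c in g.calls[:, j])
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
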