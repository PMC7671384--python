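"""Readers and writers for every external file format the pipeline touches.

Formats
-------
- SNP list: plain text, one rsID per line.
- Proxies TSV: ``lead_rsid  proxy_rsid  chrom  pos  r2`` (pos 1-based).
- Genes TSV: ``gene_id  symbol  chrom  start  end  strand [tss]``
  (start/end 0-based half-open; tss 1-based, derived from strand if absent).
- Segmentation BED: ``chrom  start  end  state  epigenome_id`` (headerless
  BED accepted; a headered TSV with the same columns also parses).
- Interactions TSV: ``chrom_a start_a end_a chrom_b start_b end_b tissue [score]``.
- QTL compendium TSV: ``qtl_class rsid target p_value tissue_or_source [effect]``.
- Summary-stats TSV: ``rsid chrom pos beta varbeta``.
- Expression TSV: first column gene id, remaining columns samples, "NA" for
  missing.
- Pathways: standard GMT.
- Summary bundles: one JSON file per lead SNP.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .types import (
    AssocStats,
    CandidateGene,
    CandidateGeneSet,
    EqtlResult,
    GeneRecord,
    GenomicInterval,
    GenotypeVector,
    InteractionRecord,
    LdRegion,
    PathwayCollection,
    ProxyRecord,
    QtlRecord,
    SegmentationRecord,
    SnpRecord,
    StaticQtlHit,
    SummaryBundle,
    ExpressionMatrix,
)

_RSID_RE = re.compile(r"^rs\d+$")


def read_snp_list(path: str | Path) -> list[str]:
    """Read a list of rsIDs, one per line, de-duplicated in first-seen order."""
    lines = Path(path).read_text().splitlines()
    seen: dict[str, None] = {}
    any_token = False
    for lineno, raw in enumerate(lines, start=1):
        token = raw.strip()
        if not token:
            continue
        any_token = True
        if not _RSID_RE.match(token):
            raise ValueError(
                f"{path}: line {lineno}: {token!r} is not an rsID (rs + digits)"
            )
        seen.setdefault(token, None)
    if not any_token:
        raise ValueError(f"{path}: no SNPs")
    return list(seen)


_SCHEMA_COLUMNS = {
    "proxies": ["lead_rsid", "proxy_rsid", "chrom", "pos", "r2"],
    "genes": ["gene_id", "symbol", "chrom", "start", "end", "strand"],
    "segmentation": ["chrom", "start", "end", "state", "epigenome_id"],
    "interactions": [
        "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "tissue",
    ],
    "qtl": ["qtl_class", "rsid", "target", "p_value", "tissue_or_source"],
    "summary_stats": ["rsid", "chrom", "pos", "beta", "varbeta"],
}


def _load_tsv(path: Path, schema: str) -> pd.DataFrame:
    required = _SCHEMA_COLUMNS[schema]
    if schema == "segmentation":
        with open(path) as fh:
            first = fh.readline()
        if first.split("\t")[0].strip() == "chrom":
            df = pd.read_csv(path, sep="\t")
        else:
            df = pd.read_csv(path, sep="\t", header=None, names=required)
    else:
        df = pd.read_csv(path, sep="\t")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def read_table(path: str | Path, schema: str):
    """Read a typed record list (or AssocStats for ``summary_stats``).

    Rows are materialized into the corresponding domain type with invariants
    checked; a violated invariant raises with the offending row number.
    """
    path = Path(path)
    if schema not in _SCHEMA_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}")
    df = _load_tsv(path, schema)

    def _row_error(i: int, exc: Exception) -> ValueError:
        return ValueError(f"{path}: row {i + 1}: {exc}")

    records: list = []
    if schema == "proxies":
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                records.append(
                    ProxyRecord(
                        lead_rsid=str(row.lead_rsid),
                        proxy_rsid=str(row.proxy_rsid),
                        chrom=str(row.chrom),
                        pos=int(row.pos),
                        r2=float(row.r2),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise _row_error(i, exc) from exc
    elif schema == "genes":
        has_tss = "tss" in df.columns
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                interval = GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end)
                )
                strand = str(row.strand)
                if has_tss and not pd.isna(row.tss):
                    tss = int(row.tss)
                else:
                    # strand decides which end of the body the TSS sits on
                    tss = interval.start + 1 if strand == "+" else interval.end
                records.append(
                    GeneRecord(
                        gene_id=str(row.gene_id),
                        symbol=str(row.symbol),
                        interval=interval,
                        tss=tss,
                        strand=strand,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise _row_error(i, exc) from exc
    elif schema == "segmentation":
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                records.append(
                    SegmentationRecord(
                        epigenome_id=str(row.epigenome_id),
                        interval=GenomicInterval(
                            str(row.chrom), int(row.start), int(row.end)
                        ),
                        state=str(row.state),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise _row_error(i, exc) from exc
    elif schema == "interactions":
        has_score = "score" in df.columns
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                records.append(
                    InteractionRecord(
                        anchor_a=GenomicInterval(
                            str(row.chrom_a), int(row.start_a), int(row.end_a)
                        ),
                        anchor_b=GenomicInterval(
                            str(row.chrom_b), int(row.start_b), int(row.end_b)
                        ),
                        tissue=str(row.tissue),
                        score=float(row.score)
                        if has_score and not pd.isna(row.score)
                        else None,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise _row_error(i, exc) from exc
    elif schema == "qtl":
        has_effect = "effect" in df.columns
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                records.append(
                    QtlRecord(
                        qtl_class=str(row.qtl_class),
                        rsid=str(row.rsid),
                        target=str(row.target),
                        p_value=float(row.p_value),
                        tissue_or_source=str(row.tissue_or_source),
                        effect=float(row.effect)
                        if has_effect and not pd.isna(row.effect)
                        else None,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise _row_error(i, exc) from exc
    elif schema == "summary_stats":
        try:
            return AssocStats(
                trait_id=path.stem,
                snps=[str(s) for s in df["rsid"]],
                positions=df["pos"].to_numpy(dtype=int),
                beta=df["beta"].to_numpy(dtype=float),
                varbeta=df["varbeta"].to_numpy(dtype=float),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return records


def read_expression(path: str | Path, tissue: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples TPM matrix; "NA" cells become missing (NaN)."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell: {exc}") from exc
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative TPM value")
    if tissue is None:
        tissue = path.stem.removeprefix("expression_")
    return ExpressionMatrix(tissue=tissue, values=values)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: per line ``id <tab> description <tab> gene...``."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT line needs >= 3 tab-separated fields"
            )
        pid, desc, members = fields[0], fields[1], fields[2:]
        if pid in pathways:
            raise ValueError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
        pathways[pid] = (desc, frozenset(m for m in members if m))
    return PathwayCollection(pathways=pathways)


def read_genotypes(path: str | Path) -> list[GenotypeVector]:
    """Read a dosage TSV: first column rsid, remaining columns samples (0/1/2)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [str(c) for c in df.columns]
    return [
        GenotypeVector(
            rsid=str(rsid), samples=samples, dosages=row.to_numpy(dtype=int)
        )
        for rsid, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Summary-bundle JSON serialization
# ---------------------------------------------------------------------------


def _interval_to_dict(iv: GenomicInterval) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end}


def _interval_from_dict(d: dict) -> GenomicInterval:
    return GenomicInterval(d["chrom"], d["start"], d["end"])


def _gene_to_dict(g: GeneRecord) -> dict:
    return {
        "gene_id": g.gene_id,
        "symbol": g.symbol,
        "interval": _interval_to_dict(g.interval),
        "tss": g.tss,
        "strand": g.strand,
    }


def _gene_from_dict(d: dict) -> GeneRecord:
    return GeneRecord(
        gene_id=d["gene_id"],
        symbol=d["symbol"],
        interval=_interval_from_dict(d["interval"]),
        tss=d["tss"],
        strand=d["strand"],
    )


def bundle_to_dict(bundle: SummaryBundle) -> dict:
    return {
        "snp": asdict(bundle.snp),
        "region": {
            "lead": asdict(bundle.region.lead),
            "proxies": [asdict(p) for p in bundle.region.proxies],
            "span": _interval_to_dict(bundle.region.span),
            "r2_threshold": bundle.region.r2_threshold,
        },
        "candidate_genes": {
            "window_genes": [_gene_to_dict(g) for g in bundle.candidate_genes.window_genes],
            "interaction_genes": [
                _gene_to_dict(g) for g in bundle.candidate_genes.interaction_genes
            ],
            "all": [
                {"gene": _gene_to_dict(c.gene), "provenance": c.provenance}
                for c in bundle.candidate_genes.all
            ],
        },
        "eqtls": [asdict(e) for e in bundle.eqtls],
        "static_qtl_hits": [
            {"record": asdict(h.record), "on_lead": h.on_lead}
            for h in bundle.static_qtl_hits
        ],
        "segment_states": {
            epi: [
                {
                    "epigenome_id": s.epigenome_id,
                    "interval": _interval_to_dict(s.interval),
                    "state": s.state,
                }
                for s in segs
            ]
            for epi, segs in bundle.segment_states.items()
        },
        "interactions": [
            {
                "anchor_a": _interval_to_dict(i.anchor_a),
                "anchor_b": _interval_to_dict(i.anchor_b),
                "tissue": i.tissue,
                "score": i.score,
            }
            for i in bundle.interactions
        ],
    }


def bundle_from_dict(d: dict) -> SummaryBundle:
    region = d["region"]
    return SummaryBundle(
        snp=SnpRecord(**d["snp"]),
        region=LdRegion(
            lead=SnpRecord(**region["lead"]),
            proxies=tuple(ProxyRecord(**p) for p in region["proxies"]),
            span=_interval_from_dict(region["span"]),
            r2_threshold=region["r2_threshold"],
        ),
        candidate_genes=CandidateGeneSet(
            window_genes=[
                _gene_from_dict(g) for g in d["candidate_genes"]["window_genes"]
            ],
            interaction_genes=[
                _gene_from_dict(g) for g in d["candidate_genes"]["interaction_genes"]
            ],
            all=[
                CandidateGene(gene=_gene_from_dict(c["gene"]), provenance=c["provenance"])
                for c in d["candidate_genes"]["all"]
            ],
        ),
        eqtls=[EqtlResult(**e) for e in d["eqtls"]],
        static_qtl_hits=[
            StaticQtlHit(record=QtlRecord(**h["record"]), on_lead=h["on_lead"])
            for h in d["static_qtl_hits"]
        ],
        segment_states={
            epi: [
                SegmentationRecord(
                    epigenome_id=s["epigenome_id"],
                    interval=_interval_from_dict(s["interval"]),
                    state=s["state"],
                )
                for s in segs
            ]
            for epi, segs in d["segment_states"].items()
        },
        interactions=[
            InteractionRecord(
                anchor_a=_interval_from_dict(i["anchor_a"]),
                anchor_b=_interval_from_dict(i["anchor_b"]),
                tissue=i["tissue"],
                score=i["score"],
            )
            for i in d["interactions"]
        ],
    )


def write_bundle(bundle: SummaryBundle, dir: str | Path) -> Path:
    """Serialize one bundle to ``<dir>/<rsid>.json``; returns the path."""
    out = Path(dir) / f"{bundle.snp.rsid}.json"
    out.write_text(json.dumps(bundle_to_dict(bundle), indent=1, sort_keys=True))
    return out


def read_bundle(path: str | Path) -> SummaryBundle:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
        return bundle_from_dict(data)
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"corrupt bundle file {path}: {exc}") from exc


def write_assoc_stats(stats: AssocStats, path: str | Path, chrom: str = "chr1") -> Path:
    """Write summary statistics in the trait TSV dialect read_table expects."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "rsid": stats.snps,
            "chrom": chrom,
            "pos": stats.positions,
            "beta": stats.beta,
            "varbeta": stats.varbeta,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path
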