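"""Static report export: a self-contained HTML page plus a JSON mirror.

The report aggregates whatever stages have run: per-SNP sections (LD region,
candidate genes, static QTL hits, segmentation states, interactions), the
per-tissue module and enrichment tables, the pathway-by-tissue matrix and
the per-SNP colocalization posterior track rendered as a static figure.
Every table shown in the HTML is mirrored field-for-field in report.json.
"""

from __future__ import annotations

import base64
import io as _io
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import io as lio


def _coloc_figure(track: pd.DataFrame, title: str) -> str:
    """Render a per-SNP causal-posterior track to a base64 PNG data URI."""
    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.scatter(track["pos"], track["h4_posterior"], s=12, color="#31688e")
    best = track.loc[track["h4_posterior"].idxmax()]
    ax.annotate(
        str(best["rsid"]),
        (best["pos"], best["h4_posterior"]),
        textcoords="offset points",
        xytext=(4, -2),
        fontsize=8,
    )
    ax.set_xlabel("genomic position")
    ax.set_ylabel("P(causal)")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def build_report(out_dir: str | Path) -> tuple[Path, Path]:
    """Assemble report.html and report.json from a run's output directory."""
    out_dir = Path(out_dir)
    bundle_paths = sorted((out_dir / "bundles").glob("*.json"))
    analysis_path = out_dir / "analysis" / "analysis.json"
    coloc_paths = sorted((out_dir / "coloc").glob("coloc_*.json"))
    if not bundle_paths and not analysis_path.is_file() and not coloc_paths:
        raise FileNotFoundError(
            f"no pipeline outputs under {out_dir}: expected bundles/, "
            "analysis/ or coloc/"
        )

    payload: dict = {"snps": {}, "analysis": None, "coloc": []}
    html: list[str] = [
        "<!doctype html><html><head><meta charset='utf-8'>",
        "<title>locus report</title>",
        "<style>body{font-family:sans-serif;margin:2em}"
        "table{border-collapse:collapse;font-size:12px}"
        "td,th{border:1px solid #999;padding:2px 6px}</style></head><body>",
        "<h1>Locus interpretation report</h1>",
    ]

    if analysis_path.is_file():
        analysis = json.loads(analysis_path.read_text())
        payload["analysis"] = analysis
        html.append("<h2>Co-expression modules and pathway enrichment</h2>")
        for tissue, res in analysis["tissues"].items():
            html.append(
                f"<h3>{tissue}: K={res['k']}, retained modules "
                f"{res['retained_modules']}</h3>"
            )
            enr = pd.DataFrame(res["enrichment"])
            if not enr.empty:
                html.append(enr.to_html(index=False))
        agg = pd.DataFrame(analysis["aggregate"])
        html.append("<h2>Pathway by tissue (all SNPs)</h2>")
        if not agg.empty:
            html.append(agg.to_html(index=False))

    for path in bundle_paths:
        bundle = lio.read_bundle(path)
        d = lio.bundle_to_dict(bundle)
        payload["snps"][bundle.snp.rsid] = d
        html.append(f"<h2>SNP {bundle.snp.rsid}</h2>")
        span = bundle.region.span
        html.append(
            f"<p>LD region {span.chrom}:{span.start}-{span.end} "
            f"({len(bundle.region.proxies)} proxies at "
            f"r&sup2; &ge; {bundle.region.r2_threshold}); "
            f"{len(bundle.candidate_genes.all)} candidate genes; "
            f"{len(bundle.eqtls)} eQTL tests; "
            f"{len(bundle.static_qtl_hits)} static QTL hits; "
            f"{sum(len(v) for v in bundle.segment_states.values())} "
            "overlapping segmentation blocks.</p>"
        )
        if bundle.eqtls:
            edf = pd.DataFrame(
                [
                    {
                        "gene": e.gene_id,
                        "tissue": e.tissue,
                        "beta": e.beta,
                        "se": e.se,
                        "p": e.p_value,
                    }
                    for e in sorted(bundle.eqtls, key=lambda e: e.p_value)[:15]
                ]
            )
            html.append(edf.to_html(index=False))

    for cpath in coloc_paths:
        cdata = json.loads(cpath.read_text())
        track_path = cpath.with_name(cpath.stem + "_track.tsv")
        track = pd.read_csv(track_path, sep="\t")
        cdata["track"] = track.to_dict(orient="records")
        payload["coloc"].append(cdata)
        html.append(
            f"<h2>Colocalization: {cdata['trait1']} vs {cdata['trait2']}</h2>"
        )
        pp = pd.DataFrame([cdata["pp"]])
        html.append(pp.to_html(index=False))
        uri = _coloc_figure(
            track, f"per-SNP causal posterior ({cdata['trait1']} / {cdata['trait2']})"
        )
        html.append(f"<img src='{uri}' alt='coloc track'/>")

    html.append("</body></html>")
    html_path = out_dir / "report.html"
    json_path = out_dir / "report.json"
    html_path.write_text("\n".join(html))
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return html_path, json_path
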