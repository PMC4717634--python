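"""Flat-file input/output.

All formats are tab-separated text with a header row, mirroring the usual
shapes of the upstream tools: gene models as a 4-column exon-interval
table, domain alignments as BLAST-tabular-like rows, variant sites /
conservation / pathogenic / de novo tables as plain per-row TSVs, and the
substitution-rate table as (context, alt, rate). Writers and readers are
exact inverses for every table the synthetic generator emits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hotzone import DeNovoMutation
from .pathogenic import ClinicalVariant
from .regions import DomainAlignment, GeneModel, SubRegion
from .scores import SiteRecord

__all__ = [
    "read_gene_models", "write_gene_models",
    "read_alignments", "write_alignments",
    "read_regions", "write_regions",
    "read_sites", "write_sites",
    "read_conservation", "write_conservation",
    "read_rate_table", "write_rate_table",
    "read_pathogenic", "write_pathogenic",
    "read_denovo", "write_denovo",
    "read_scores", "write_scores",
    "write_cohort",
    "read_sequences", "write_sequences",
]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "exons": ",".join(f"{s}-{e}" for s, e in g.coding_exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        exons = tuple(
            (int(p.split("-")[0]), int(p.split("-")[1])) for p in row.exons.split(",")
        )
        out[row.gene_id] = GeneModel(row.gene_id, row.chrom, row.strand, exons)
    return out


def write_alignments(alignments: Iterable[DomainAlignment], path: str | Path) -> None:
    rows = [
        {
            "gene_id": a.gene_id,
            "domain_id": a.domain_id,
            "aa_start": a.aa_start,
            "aa_end": a.aa_end,
            "evalue": a.evalue,
            "bit_score": a.score,
        }
        for a in alignments
    ]
    pd.DataFrame(rows, columns=["gene_id", "domain_id", "aa_start", "aa_end", "evalue", "bit_score"]).to_csv(
        path, sep="\t", index=False
    )


def read_alignments(path: str | Path) -> list[DomainAlignment]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        DomainAlignment(r.gene_id, r.domain_id, int(r.aa_start), int(r.aa_end), float(r.evalue), float(r.bit_score))
        for r in df.itertuples(index=False)
    ]


def write_regions(regions: Iterable[SubRegion], genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """BED-like region table: genomic span plus CDS-space interval and
    exon-split block structure."""
    rows = []
    for r in regions:
        g = genes[r.gene_id]
        gmin = min(s for s, _ in r.genomic_blocks)
        gmax = max(e for _, e in r.genomic_blocks)
        rows.append(
            {
                "chrom": g.chrom,
                "start": gmin,
                "end": gmax,
                "gene_id": r.gene_id,
                "region_index": r.index,
                "label": r.label,
                "cds_start": r.cds_start,
                "cds_end": r.cds_end,
                "blocks": ",".join(f"{s}-{e}" for s, e in r.genomic_blocks),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[SubRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"blocks": str, "label": str}, float_precision="round_trip")
    out = []
    for r in df.itertuples(index=False):
        blocks = tuple((int(p.split("-")[0]), int(p.split("-")[1])) for p in r.blocks.split(","))
        out.append(
            SubRegion(
                gene_id=r.gene_id,
                index=int(r.region_index),
                label=r.label,
                cds_start=int(r.cds_start),
                cds_end=int(r.cds_end),
                genomic_blocks=blocks,
            )
        )
    return out


def write_sites(sites: Iterable[SiteRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "mean_coverage": s.mean_coverage,
            "filter": s.filter_status,
            "is_variant": int(s.is_variant),
            "maf": s.alt_allele_frequency,
            "consequence": s.consequence,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> list[SiteRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        SiteRecord(
            chrom=r.chrom,
            pos=int(r.pos),
            mean_coverage=float(r.mean_coverage),
            filter_status=r.filter,
            is_variant=bool(r.is_variant),
            alt_allele_frequency=float(r.maf),
            consequence=r.consequence,
        )
        for r in df.itertuples(index=False)
    ]


def write_conservation(conservation: Mapping[str, Mapping[int, float]], path: str | Path) -> None:
    rows = [
        {"chrom": chrom, "pos": pos, "score": score}
        for chrom, track in conservation.items()
        for pos, score in sorted(track.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "score"]).to_csv(path, sep="\t", index=False)


def read_conservation(path: str | Path) -> dict[str, dict[int, float]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict[str, dict[int, float]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.chrom, {})[int(r.pos)] = float(r.score)
    return out


def write_rate_table(table: Mapping[tuple[str, str], float], path: str | Path) -> None:
    rows = [
        {"context": ctx, "alt": alt, "rate": rate}
        for (ctx, alt), rate in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["context", "alt", "rate"]).to_csv(path, sep="\t", index=False)


def read_rate_table(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {(r.context, r.alt): float(r.rate) for r in df.itertuples(index=False)}


def write_pathogenic(variants: Iterable[ClinicalVariant], path: str | Path) -> None:
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "source": v.source,
            "clinical_label": v.clinical_label,
            "canonical": int(v.canonical),
            "consequence_terms": ",".join(sorted(v.consequence_terms)),
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pathogenic(path: str | Path) -> list[ClinicalVariant]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        ClinicalVariant(
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            source=r.source,
            clinical_label=r.clinical_label,
            canonical=bool(r.canonical),
            consequence_terms=frozenset(str(r.consequence_terms).split(",")),
        )
        for r in df.itertuples(index=False)
    ]


def write_denovo(mutations: Iterable[DeNovoMutation], path: str | Path) -> None:
    rows = [
        {
            "chrom": m.chrom,
            "pos": m.pos,
            "consequence": m.consequence,
            "polyphen2_humvar": "" if m.polyphen2_humvar is None else m.polyphen2_humvar,
            "cohort": m.cohort,
            "in_both_siblings": int(m.in_both_siblings),
            "validated_by": ",".join(sorted(m.validated_by)),
            "call_labels": json.dumps(dict(m.call_labels or {}), sort_keys=True),
        }
        for m in mutations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_denovo(path: str | Path) -> list[DeNovoMutation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    out = []
    for r in df.itertuples(index=False):
        pp = r.polyphen2_humvar
        out.append(
            DeNovoMutation(
                chrom=r.chrom,
                pos=int(r.pos),
                consequence=r.consequence,
                polyphen2_humvar=None if pp == "" else float(pp),
                cohort=r.cohort,
                in_both_siblings=bool(int(r.in_both_siblings)),
                validated_by=frozenset(x for x in r.validated_by.split(",") if x),
                call_labels=json.loads(r.call_labels) if r.call_labels else None,
            )
        )
    return out


def write_scores(scores: pd.Series | pd.DataFrame, path: str | Path) -> None:
    """Region score table keyed by (gene_id, region_index); one column per
    score kind."""
    df = scores.to_frame() if isinstance(scores, pd.Series) else scores
    df.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    return df.set_index(["gene_id", "region_index"])


def write_sequences(flanked_cds: Mapping[str, str], path: str | Path) -> None:
    """Flanked CDS sequences as FASTA (one record per gene; the sequence is
    the CDS with one extra base on each side)."""
    with open(path, "w") as fh:
        for gid in sorted(flanked_cds):
            fh.write(f">{gid}\n")
            seq = flanked_cds[gid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_sequences(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_cohort(cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every table of a synthetic cohort to ``outdir``; returns the
    path of each emitted file. Includes a truth JSON of planted
    parameters and intolerant region keys."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "alignments": outdir / "alignments.tsv",
        "regions": outdir / "regions_domain.tsv",
        "sites": outdir / "sites.tsv",
        "conservation": outdir / "conservation.tsv",
        "rate_table": outdir / "rate_table.tsv",
        "pathogenic": outdir / "pathogenic.tsv",
        "denovo": outdir / "denovo.tsv",
        "sequences": outdir / "cds_flanked.fasta",
        "truth": outdir / "truth.json",
    }
    write_gene_models(cohort.genes.values(), paths["genes"])
    write_alignments([a for alns in cohort.alignments.values() for a in alns], paths["alignments"])
    write_regions(cohort.domain_regions, cohort.genes, paths["regions"])
    write_sites(cohort.sites, paths["sites"])
    write_conservation(cohort.conservation, paths["conservation"])
    write_rate_table(cohort.rate_table, paths["rate_table"])
    write_pathogenic(cohort.pathogenic, paths["pathogenic"])
    write_denovo(cohort.denovo, paths["denovo"])
    write_sequences(cohort.flanked_cds, paths["sequences"])
    truth = {
        "config": {k: v for k, v in vars(cohort.config).items()},
        "intolerant_regions": sorted([gid, idx] for gid, idx in cohort.intolerant_keys),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
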