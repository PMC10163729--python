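"""Plain-text I/O: SAM-like read TSV, BED-like panel, YAML config, reports.

All tabular text uses 1-based inclusive start coordinates (BED-style
``end`` stays exclusive in the panel file, as in BED); in-memory objects
are 0-based half-open.  Reads are exchanged as a SAM-like TSV because
the read model carries locus-level allele calls rather than base-level
sequences; the UMI pair travels in a tag-style column (``RX:u1-u2``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import yaml

from .calling import PerformanceReport, VariantCall
from .collision import CollisionReport, SignalLossReport
from .grouping import ReadGroup
from .simulate import (
    FragmentationModel,
    Locus,
    PanelDefinition,
    ReadRecord,
    SimulationConfig,
)

READ_COLUMNS = (
    "read_id", "contig", "start_1based", "end", "strand", "umi", "molecule_id",
    "calls",
)


def _format_calls(calls: dict[int, str]) -> str:
    if not calls:
        return "."
    return ";".join(f"{pos + 1}:{allele}" for pos, allele in sorted(calls.items()))


def _parse_calls(text: str) -> dict[int, str]:
    if text == ".":
        return {}
    out: dict[int, str] = {}
    for item in text.split(";"):
        pos, allele = item.split(":")
        out[int(pos) - 1] = allele
    return out


def write_reads_tsv(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(READ_COLUMNS) + "\n")
        for r in reads:
            umi = f"RX:{r.umi_observed[0]}-{r.umi_observed[1]}" if r.has_umi else "."
            fh.write(
                "\t".join(
                    (
                        r.read_id,
                        r.contig,
                        str(r.start + 1),
                        str(r.end),
                        r.strand,
                        umi,
                        str(r.molecule_id),
                        _format_calls(dict(r.calls)),
                    )
                )
                + "\n"
            )


def read_reads_tsv(path: str | Path) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            (read_id, contig, start1, end, strand, umi, mol_id, calls) = (
                line.rstrip("\n").split("\t")
            )
            if umi == ".":
                pair = ("", "")
            else:
                u1, u2 = umi.removeprefix("RX:").split("-")
                pair = (u1, u2)
            reads.append(
                ReadRecord(
                    read_id=read_id,
                    contig=contig,
                    start=int(start1) - 1,
                    end=int(end),
                    strand=strand,  # type: ignore[arg-type]
                    umi_observed=pair,
                    calls=_parse_calls(calls),
                    molecule_id=int(mol_id),
                )
            )
    return reads


def write_panel_bed(panel: PanelDefinition, path: str | Path) -> None:
    """BED-like TSV: contig, 0-based start, end, ref, alt, class; a
    header comment carries the interrogated span."""
    with open(path, "w") as fh:
        fh.write(f"#interrogated_span_bp={panel.interrogated_span_bp}\n")
        fh.write("#contig\tstart\tend\tref\talt\tvariant_class\n")
        for locus in panel.loci:
            fh.write(
                f"{locus.contig}\t{locus.pos}\t{locus.pos + 1}\t"
                f"{locus.ref}\t{locus.alt}\t{locus.variant_class}\n"
            )


def read_panel_bed(path: str | Path) -> PanelDefinition:
    span = 0
    loci: list[Locus] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#interrogated_span_bp="):
                span = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            contig, start, _end, ref, alt, vc = line.split("\t")
            loci.append(Locus(contig, int(start), ref, alt, vc))  # type: ignore[arg-type]
    if span == 0:
        span = max(l.pos for l in loci) + 1 if loci else 1
    return PanelDefinition(tuple(loci), span)


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d.pop("panel")
    return d


def write_config_yaml(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def read_config_yaml(path: str | Path, panel: PanelDefinition) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    frag = FragmentationModel(**data.pop("fragmentation"))
    return SimulationConfig(panel=panel, fragmentation=frag, **data)


def write_calls_tsv(
    calls: Iterable[VariantCall], path: str | Path
) -> None:
    """Minimal VCF-like TSV (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("#contig\tpos\tref\talt\tn_support\ttotal_molecules\n")
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t{c.ref}\t{c.alt}\t"
                f"{c.n_support}\t{c.total}\n"
            )


def write_grouping_tsv(groups: Iterable[ReadGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#contig\tstart\tend\tumi_cluster_id\tn_reads_top\t"
            "n_reads_bottom\tduplexity\n"
        )
        for g in groups:
            contig, start, end = g.key.fragment_key
            cid = g.key.umi_cluster_id or "."
            fh.write(
                f"{contig}\t{start + 1}\t{end}\t{cid}\t{g.n_top}\t"
                f"{g.n_bottom}\t{g.duplexity}\n"
            )


def report_to_dict(report: PerformanceReport) -> dict[str, Any]:
    return {
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "fp_per_kb": report.fp_per_kb,
        "auc": report.auc,
        "roc_points": [list(p) for p in report.roc_points],
    }


def collision_to_dict(report: CollisionReport) -> dict[str, Any]:
    return {
        "n_position_groups": report.n_position_groups,
        "n_umi_molecules": report.n_umi_molecules,
        "n_colliding_groups": report.n_colliding_groups,
        "collision_rate": report.collision_rate,
        "count_discrepancy": report.count_discrepancy,
    }


def signal_loss_to_dict(report: SignalLossReport) -> dict[str, Any]:
    return {
        "total_input_ng": report.total_input_ng,
        "fraction_lost": report.fraction_lost,
        "n_alt_with_umi": sum(report.n_alt_with_umi.values()),
        "n_alt_position_only": sum(report.n_alt_position_only.values()),
    }


def write_json(data: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
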