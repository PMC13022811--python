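"""Reading caller VCFs and writing PEP-annotated results.

All parsing and writing goes through :mod:`pysam`; coordinates follow the
VCF convention (1-based, inclusive END).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .callset import CallMatrix, MergePolicy, SVCall, ToolMeta, normalize_svtype

__all__ = [
    "parse_vcf",
    "write_annotated_output",
    "read_annotated_vcf",
    "load_tool_config",
]

logger = logging.getLogger(__name__)


def _record_svtype(rec) -> str:
    token = rec.info.get("SVTYPE") if "SVTYPE" in rec.info else None
    if token is None and rec.alts:
        alt = rec.alts[0]
        if alt.startswith("<") and alt.endswith(">"):
            token = alt.strip("<>").split(":")[0]
        elif "[" in alt or "]" in alt:
            token = "BND"
        elif rec.ref is not None and len(alt) != len(rec.ref):
            token = "INS" if len(alt) > len(rec.ref) else "DEL"
    return normalize_svtype(token)


def _record_svlen(rec, svtype: str, pos: int, end: int) -> int:
    if "SVLEN" in rec.info:
        svlen = rec.info["SVLEN"]
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        try:
            return int(svlen)
        except (TypeError, ValueError):
            pass
    if svtype == "INS" and rec.alts and not rec.alts[0].startswith("<"):
        return len(rec.alts[0]) - len(rec.ref or "")
    if svtype == "DEL":
        return -(end - pos)
    return end - pos


def _record_score(rec, tool: ToolMeta) -> Optional[float]:
    if not tool.has_score:
        return None
    if tool.score_field.upper() == "QUAL":
        return None if rec.qual is None else float(rec.qual)
    val = rec.info.get(tool.score_field) if tool.score_field in rec.info else None
    if isinstance(val, (tuple, list)):
        val = val[0] if val else None
    if val in (None, "."):
        return None
    try:
        return float(val)
    except (TypeError, ValueError):
        return None


def parse_vcf(
    path,
    tool: ToolMeta,
    tool_id: int = 0,
    accept_all_filters: bool = False,
    stats: Optional[dict] = None,
) -> list[SVCall]:
    """Extract SV calls from one caller's VCF (plain or bgzipped).

    By default only records whose FILTER is PASS or missing are kept; records
    failing a filter, or with unusable coordinates, are skipped with a logged
    warning and counted in ``stats`` (keys ``filtered`` / ``skipped``).
    """
    if stats is None:
        stats = {}
    stats.setdefault("parsed", 0)
    stats.setdefault("filtered", 0)
    stats.setdefault("skipped", 0)

    calls: list[SVCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = list(rec.filter.keys())
            if not accept_all_filters and filters and filters != ["PASS"]:
                stats["filtered"] += 1
                logger.warning("%s:%s failed FILTER %s; skipped",
                               rec.chrom, rec.pos, ",".join(filters))
                continue
            try:
                pos = int(rec.pos)
                end = int(rec.stop)
                svtype = _record_svtype(rec)
                if svtype == "INS":
                    end = pos
                end = max(end, pos)
                svlen = _record_svlen(rec, svtype, pos, end)
                genotype = None
                if rec.samples:
                    sample = rec.samples[0]
                    gt = sample.get("GT")
                    if gt is not None:
                        sep = "|" if getattr(sample, "phased", False) else "/"
                        genotype = sep.join("." if g is None else str(g) for g in gt)
                calls.append(SVCall(
                    tool_id=tool_id, chrom=rec.chrom, pos=pos, end=end,
                    svtype=svtype, svlen=svlen, score=_record_score(rec, tool),
                    genotype=genotype, source_line=rec.id,
                ))
                stats["parsed"] += 1
            except (ValueError, TypeError) as exc:  # malformed record: skip
                stats["skipped"] += 1
                logger.warning("unparsable record near %s:%s (%s); skipped",
                               rec.chrom, rec.pos, exc)
    return calls


def _symbolic_alt(svtype: str) -> str:
    return f"<{svtype}>" if svtype in ("DEL", "INS", "DUP", "INV", "BND") else "<SV>"


def write_annotated_output(cm: CallMatrix, summary, report, path_prefix) -> None:
    """Write the PEP-annotated TSV and VCF for a fitted call matrix.

    ``path_prefix`` yields ``<prefix>.tsv`` and ``<prefix>.vcf``.  The VCF
    INFO fields carry END/SVTYPE/SVLEN plus PEP (posterior error
    probability), SUPP (x_i, number of supporting tools) and SUPP_VEC (the
    per-tool indicator string).
    """
    pep = np.asarray(summary.pep, dtype=float)
    if pep.shape[0] != cm.n:
        raise ValueError("PEP length does not match the call matrix")
    decisions = np.asarray(report.decisions, dtype=int) if report is not None else None

    df = cm.positions.reset_index(drop=True).copy()
    df["x"] = cm.X
    for j, t in enumerate(cm.tools):
        df[f"y_{t.name}"] = cm.Y[:, j]
    for j in cm.score_tools:
        df[f"s_{cm.tools[j].name}"] = cm.S[:, j]
    df["pep"] = pep
    if decisions is not None:
        df["decision"] = decisions
    df.to_csv(f"{path_prefix}.tsv", sep="\t", index=False, na_rep="NA",
              float_format="%.6g")

    if cm.n and (df["chrom"].isna().any() or (df["pos"] < 1).any()):
        # no genomic coordinates (e.g. a raw simulated matrix): TSV only
        logger.info("positions carry no genomic coordinates; skipping VCF")
        return

    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(df["chrom"].astype(str))) if cm.n else []
    for chrom in chroms:
        length = int(df.loc[df["chrom"].astype(str) == chrom, "end"].max()) + 10_000
        header.contigs.add(chrom, length=length)
    header.add_meta("INFO", items=[("ID", "END"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "End position of the variant")])
    header.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", 1), ("Type", "String"),
                                   ("Description", "Type of structural variant")])
    header.add_meta("INFO", items=[("ID", "SVLEN"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Signed length of the variant")])
    header.add_meta("INFO", items=[("ID", "PEP"), ("Number", 1), ("Type", "Float"),
                                   ("Description", "Posterior error probability P(z=0|data)")])
    header.add_meta("INFO", items=[("ID", "SUPP"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Number of supporting tools")])
    header.add_meta("INFO", items=[("ID", "SUPP_VEC"), ("Number", 1), ("Type", "String"),
                                   ("Description", "Per-tool support indicator string")])

    with pysam.VariantFile(f"{path_prefix}.vcf", "w", header=header) as out:
        for i in range(cm.n):
            row = df.iloc[i]
            svtype = str(row["svtype"])
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=max(int(row["end"]), int(row["pos"])),
                alleles=("N", _symbolic_alt(svtype)),
                id=f"SV{i + 1}",
            )
            rec.info["SVTYPE"] = svtype
            rec.info["SVLEN"] = int(row["svlen"])
            rec.info["PEP"] = float(pep[i])
            rec.info["SUPP"] = int(cm.X[i])
            rec.info["SUPP_VEC"] = "".join(str(v) for v in cm.Y[i])
            out.write(rec)


def read_annotated_vcf(path) -> pd.DataFrame:
    """Read back a VCF produced by :func:`write_annotated_output`."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append({
                "chrom": rec.chrom,
                "pos": int(rec.pos),
                "end": int(rec.stop),
                "svtype": rec.info.get("SVTYPE"),
                "svlen": int(rec.info.get("SVLEN", 0)),
                "pep": float(rec.info["PEP"]),
                "supp": int(rec.info["SUPP"]),
                "supp_vec": rec.info.get("SUPP_VEC"),
            })
    cols = ["chrom", "pos", "end", "svtype", "svlen", "pep", "supp", "supp_vec"]
    return pd.DataFrame(rows, columns=cols)


def load_tool_config(path):
    """Load the YAML run configuration.

    Returns ``(tools, vcf_paths, policy, accept_all_filters)`` where the YAML
    lists per-tool ``name``/``vcf``/``score_field``/``has_score``/``a``/``b``
    and optional ``merge`` policy overrides.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    tools, paths = [], []
    for entry in cfg["tools"]:
        tools.append(ToolMeta(
            name=entry["name"],
            has_score=bool(entry.get("has_score", True)),
            a=float(entry.get("a", -np.inf)),
            b=float(entry.get("b", np.inf)),
            score_field=entry.get("score_field", "QUAL"),
        ))
        paths.append(entry["vcf"])
    merge = cfg.get("merge", {})
    policy = MergePolicy(
        max_breakpoint_distance=int(merge.get("max_breakpoint_distance", 1000)),
        min_length_ratio=float(merge.get("min_length_ratio", 0.7)),
        require_same_type=bool(merge.get("require_same_type", True)),
    )
    return tools, paths, policy, bool(cfg.get("accept_all_filters", False))
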