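"""File readers/writers: dosage CSV, covariate CSV, VCF, and analysis reports.

Dosage files are headered CSV — first column ``participant_id``, one column
per rsid, values 0/1/2 or missing ("NA", "", "."; always written back as
"NA").  VCF genotypes are matched to the panel by the ID column and counted
toward the modeled allele, which must equal REF or one of the ALTs; any other
configuration is a hard error — no strand inference is attempted.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import GenotypeMatrix, SnpPanel
from .stats import AssociationReport, BaselineRow

logger = logging.getLogger("afgrs")

__all__ = [
    "read_dosage_csv",
    "write_dosage_csv",
    "read_covariates_csv",
    "read_vcf",
    "write_vcf",
    "write_report",
    "baseline_rows_to_frame",
]

NA_STRINGS = ["NA", "", "."]


def read_dosage_csv(path: str | Path, panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Read a participants x SNPs dosage CSV into a genotype matrix.

    With a panel, rsids absent from it are warned about (and kept); column
    alignment to the panel happens later at scoring time.
    """
    df = pd.read_csv(path, na_values=NA_STRINGS, keep_default_na=False, dtype=str)
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: no dosage columns found")
    ids = df.iloc[:, 0].astype(str).tolist()
    rsids = list(df.columns[1:])
    raw = df.iloc[:, 1:]
    dosage = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        for i, val in enumerate(raw[col]):
            if pd.isna(val):
                continue
            try:
                x = float(val)
            except ValueError:
                raise ValueError(f"{path}: non-dosage value {val!r} at row {i + 1}, column {col}")
            if x not in (0.0, 1.0, 2.0):
                raise ValueError(f"{path}: dosage {val!r} at row {i + 1}, column {col} not in {{0,1,2}}")
            dosage[i, j] = x
    if panel is not None:
        unknown = sorted(set(rsids) - set(panel.rsids))
        if unknown:
            logger.warning("dosage file has rsids not in panel: %s", unknown)
    return GenotypeMatrix(ids, rsids, dosage)


def write_dosage_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosage, columns=gm.rsids)
    # integer dosages written without decimals; imputed values keep theirs
    for c in df.columns:
        col = df[c]
        if np.all(np.isnan(col) | (col == np.round(col))):
            df[c] = col.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "participant_id", gm.participant_ids)
    df.to_csv(path, index=False, na_rep="NA")


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=NA_STRINGS, keep_default_na=False)
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    return df


def read_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Extract modeled-allele dosages for the panel's SNPs from a VCF.

    Records match the panel by rsid; missing GT (./.) becomes a missing
    dosage; panel SNPs absent from the file are a collected error.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = {r: j for j, r in enumerate(panel.rsids)}
    dosage = np.full((len(samples), len(panel)), np.nan)
    seen: set[str] = set()
    for rec in vcf:
        rsid = rec.ID
        if rsid not in wanted or rsid in seen:
            continue
        seen.add(rsid)
        modeled = str(panel.row(rsid)["modeled_allele"])
        alleles = [rec.REF] + list(rec.ALT)
        if modeled not in alleles:
            raise ValueError(
                f"{rsid}: modeled allele {modeled} matches neither REF={rec.REF} "
                f"nor ALT={','.join(rec.ALT) or '.'} (no strand inference attempted)"
            )
        target = alleles.index(modeled)
        j = wanted[rsid]
        for i, gt in enumerate(rec.genotypes):
            calls = [g for g in gt[:-1]]  # last element is phasing flag
            if any(c < 0 for c in calls):
                continue  # ./. -> missing
            dosage[i, j] = sum(1 for c in calls if c == target)
    absent = sorted(set(wanted) - seen)
    if absent:
        raise ValueError(f"panel SNPs absent from VCF: {absent}")
    return GenotypeMatrix(samples, list(panel.rsids), dosage)


def write_vcf(gm: GenotypeMatrix, panel: SnpPanel, path: str | Path) -> None:
    """Write dosages as a minimal VCFv4.2 with the modeled allele as ALT.

    Positions are synthetic ordinals (the panel carries cytobands, not
    coordinates); REF is an arbitrary different nucleotide.  Integer dosage d
    becomes a genotype with d copies of ALT; non-integer (imputed) dosages
    cannot be represented and are an error.
    """
    gm = gm.aligned_to(panel)
    d = gm.dosage
    obs = d[~np.isnan(d)]
    if obs.size and np.any(obs != np.round(obs)):
        raise ValueError("cannot write imputed (non-integer) dosages to VCF")
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.participant_ids),
    ]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, rsid in enumerate(gm.rsids):
        row = panel.row(rsid)
        alt = str(row["modeled_allele"])
        ref = "A" if alt != "A" else "C"
        m = re.match(r"(\d+|X|Y)", str(row["locus"]))
        chrom = m.group(1) if m else "1"
        gts = "\t".join(
            "./." if np.isnan(v) else gt_map[v] for v in d[:, j]
        )
        lines.append(f"{chrom}\t{j + 1}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def baseline_rows_to_frame(rows: list[BaselineRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "no_af": [r.summary_no_af for r in rows],
            "af": [r.summary_af for r in rows],
            "test": [r.test for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )


def _report_to_dict(rep: AssociationReport) -> dict:
    return {
        "coding": rep.coding,
        "adjusted": rep.adjusted,
        "covariates": rep.covariates,
        "terms": rep.terms.to_dict(orient="records"),
        "c_statistic_base": rep.c_statistic_base,
        "c_statistic_full": rep.c_statistic_full,
        "c_comparison_p": rep.c_comparison_p,
    }


def write_report(
    reports: list[AssociationReport],
    out_dir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    baseline: list[BaselineRow] | None = None,
) -> dict[str, Path]:
    """Write analyses as machine JSON plus per-report TSVs.

    The JSON echoes the seed, config and package version; categorical-coding
    TSVs print ``Reference`` in the lowest group's OR cell.
    """
    if not reports and baseline is None:
        raise ValueError("nothing to write: empty report list")
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    payload = {
        "seed": seed,
        "config": config or {},
        "version": __version__,
        "reports": [_report_to_dict(r) for r in reports],
    }
    if baseline is not None:
        payload["baseline"] = baseline_rows_to_frame(baseline).to_dict(orient="records")
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, default=float))
    written["json"] = json_path

    if baseline is not None:
        p = out_dir / "baseline.tsv"
        baseline_rows_to_frame(baseline).to_csv(p, sep="\t", index=False)
        written["baseline"] = p
    for i, rep in enumerate(reports):
        t = rep.terms.copy()
        if rep.coding in ("quintile", "tertile"):
            t["or_ci"] = [
                "Reference" if np.isnan(r["ci_low"]) and r["or"] == 1.0
                else f"{r['or']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
                for _, r in t.iterrows()
            ]
        name = f"association_{i}_{rep.coding}_{'adj' if rep.adjusted else 'unadj'}.tsv"
        p = out_dir / name
        t.to_csv(p, sep="\t", index=False)
        written[name] = p
    return written
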