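"""SNP weight panel and the weighted allele-counting genetic risk score.

The score for participant *j* is

    GRS_j = sum_i  w_i * g_ij

where ``g_ij`` is the dosage (0, 1 or 2 copies; real-valued after mean
imputation) of the *modeled* allele of SNP *i* and ``w_i`` its published
log-odds-scale weight.  The modeled allele is the allele whose copies are
counted; protective alleles keep their counting orientation and carry a
negative weight instead of being flipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("afgrs")

__all__ = [
    "SnpPanel",
    "GenotypeMatrix",
    "GrsVector",
    "PanelError",
    "load_panel",
    "impute_missing",
    "compute_grs",
    "assign_quantiles",
    "subset_one_per_gene",
    "AF12_ROWS",
    "AF9_KEEP",
]

PANEL_COLUMNS = ["rsid", "gene", "locus", "modeled_allele", "freq", "weight"]

# The canonical 12-SNP atrial-fibrillation panel: rsid, gene, cytoband,
# modeled allele, modeled-allele frequency, log-odds weight.
AF12_ROWS = [
    ("rs13376333", "KCNN3", "1q21", "T", 0.30, 0.12),
    ("rs3903239", "PRRX1", "1q24", "G", 0.40, 0.13),
    ("rs10033464", "PITX2", "4q25", "T", 0.10, 0.33),
    ("rs17570669", "PITX2", "4q25", "T", 0.07, -0.31),
    ("rs2200733", "PITX2", "4q25", "T", 0.13, 0.54),
    ("rs3853445", "PITX2", "4q25", "C", 0.27, -0.15),
    ("rs3807989", "CAV1", "7q31", "A", 0.42, -0.11),
    ("rs10821415", "C9orf3", "9q22", "A", 0.40, 0.10),
    ("rs10824026", "SYNPO2L", "10q22", "G", 0.18, -0.14),
    ("rs1152591", "SYNE2", "14q23", "A", 0.46, 0.12),
    ("rs7164883", "HCN4", "15q24", "G", 0.19, 0.17),
    ("rs2106261", "ZFHX3", "16q22", "T", 0.19, 0.22),
]

# One-per-gene reduction: PITX2 is the only multi-SNP gene, represented by
# its most strongly associated SNP; all other genes keep their single SNP.
AF9_KEEP = {"PITX2": "rs2200733"}

_NUCLEOTIDES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised for an invalid SNP panel or a panel/genotype mismatch."""


@dataclass(frozen=True)
class SnpPanel:
    """An ordered table of SNPs with modeled alleles, frequencies and weights."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise PanelError(f"panel is missing columns: {missing}")
        dup = t["rsid"][t["rsid"].duplicated()].tolist()
        if dup:
            raise PanelError(f"duplicate rsids in panel: {dup}")
        for _, row in t.iterrows():
            if not (0.0 < row["freq"] < 1.0):
                raise PanelError(
                    f"{row['rsid']}: modeled-allele frequency {row['freq']} "
                    "outside the open interval (0, 1)"
                )
            if not np.isfinite(row["weight"]):
                raise PanelError(f"{row['rsid']}: non-finite weight {row['weight']}")
            if row["modeled_allele"] not in _NUCLEOTIDES:
                raise PanelError(
                    f"{row['rsid']}: modeled allele {row['modeled_allele']!r} "
                    "is not a single nucleotide"
                )

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(dtype=float)

    @property
    def freqs(self) -> np.ndarray:
        return self.table["freq"].to_numpy(dtype=float)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def row(self, rsid: str) -> pd.Series:
        hit = self.table[self.table["rsid"] == rsid]
        if hit.empty:
            raise PanelError(f"rsid {rsid} not in panel")
        return hit.iloc[0]

    def weight(self, rsid: str) -> float:
        return float(self.row(rsid)["weight"])

    def score_bounds(self) -> tuple[float, float]:
        """Theoretical (min, max) score: 2x the negative / positive weight sums."""
        w = self.weights
        return 2.0 * w[w < 0].sum(), 2.0 * w[w > 0].sum()


@dataclass(frozen=True)
class GenotypeMatrix:
    """Participants x SNPs modeled-allele dosages; NaN marks a missing genotype."""

    participant_ids: list[str]
    rsids: list[str]
    dosage: np.ndarray  # float, shape (n_participants, n_snps)

    def __post_init__(self) -> None:
        d = np.asarray(self.dosage, dtype=float)
        object.__setattr__(self, "dosage", d)
        if d.shape != (len(self.participant_ids), len(self.rsids)):
            raise ValueError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.participant_ids)} participants x {len(self.rsids)} SNPs"
            )
        obs = d[~np.isnan(d)]
        if obs.size and (np.any(obs < 0) or np.any(obs > 2)):
            bad = obs[(obs < 0) | (obs > 2)][0]
            raise ValueError(f"dosage value {bad} outside [0, 2]")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def missing_rate(self) -> float:
        return self.n_missing / self.dosage.size

    def aligned_to(self, panel: SnpPanel) -> "GenotypeMatrix":
        """Reorder columns to panel order, failing on any rsid mismatch."""
        unmatched = sorted(set(panel.rsids) ^ set(self.rsids))
        if unmatched:
            raise PanelError(f"rsid mismatch between genotypes and panel: {unmatched}")
        if self.rsids == panel.rsids:
            return self
        order = [self.rsids.index(r) for r in panel.rsids]
        return GenotypeMatrix(self.participant_ids, list(panel.rsids), self.dosage[:, order])


@dataclass(frozen=True)
class GrsVector:
    """Per-participant scores plus optional quintile/tertile stratification."""

    participant_ids: list[str]
    score: np.ndarray
    quintile: np.ndarray | None = None
    tertile: np.ndarray | None = None
    quintile_bounds: np.ndarray | None = None
    tertile_bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.score, dtype=float)
        object.__setattr__(self, "score", s)
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite (impute missing genotypes first)")


def load_panel(source: str) -> SnpPanel:
    """Load a SNP weight panel from a built-in name or a delimited file.

    ``"af12"`` is the canonical 12-SNP panel; ``"af9"`` its one-per-gene
    subset (PITX2 represented by rs2200733, weights unchanged).  Any other
    string is a CSV/TSV path with columns rsid, gene, locus, modeled_allele,
    freq, weight.
    """
    if source == "af12":
        return SnpPanel(pd.DataFrame(AF12_ROWS, columns=PANEL_COLUMNS))
    if source == "af9":
        return subset_one_per_gene(load_panel("af12"), AF9_KEEP)
    sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(source, sep=sep)
    table.columns = [c.strip().lower() for c in table.columns]
    return SnpPanel(table[PANEL_COLUMNS].copy())


def impute_missing(gm: GenotypeMatrix, panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Replace each missing dosage with the observed column mean (additive coding).

    A column with no observed genotypes is an error unless ``panel`` is given,
    in which case it falls back to the Hardy-Weinberg expectation
    ``2 * modeled_allele_freq`` (logged).
    """
    if gm.n_missing == 0:
        return gm
    d = gm.dosage.copy()
    for j, rsid in enumerate(gm.rsids):
        col = d[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            if panel is None:
                raise ValueError(
                    f"{rsid}: no observed genotypes to impute from "
                    "(supply a panel for the 2*freq fallback)"
                )
            fill = 2.0 * float(panel.row(rsid)["freq"])
            logger.warning("%s: column fully missing, imputing 2*freq = %.3f", rsid, fill)
        else:
            fill = float(obs.mean())
        col[miss] = fill
    return GenotypeMatrix(gm.participant_ids, gm.rsids, d)


def compute_grs(gm: GenotypeMatrix, panel: SnpPanel) -> GrsVector:
    """Weighted allele count: score_j = sum_i w_i * dosage_ij."""
    gm = gm.aligned_to(panel)
    if gm.n_missing:
        raise ValueError(
            f"{gm.n_missing} missing dosages; run impute_missing before scoring"
        )
    return GrsVector(gm.participant_ids, gm.dosage @ panel.weights)


def _quantile_labels(scores: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    if np.unique(scores).size < k:
        raise ValueError(f"fewer than {k} distinct scores; cannot form {k} groups")
    bounds = np.quantile(scores, np.arange(1, k) / k)  # type-7 interpolation
    # Closed-upper intervals: score <= bound falls in the lower group.
    labels = 1 + np.sum(scores[:, None] > bounds[None, :], axis=1)
    return labels.astype(int), bounds


def assign_quantiles(grs: GrsVector, k: int) -> GrsVector:
    """Attach quintile (k=5) or tertile (k=3) labels and cut points.

    Cut points are type-7 sample quantiles; membership uses closed upper
    bounds, so ties can make group sizes unequal.
    """
    if k not in (3, 5):
        raise ValueError(f"k must be 3 or 5, got {k}")
    labels, bounds = _quantile_labels(grs.score, k)
    kwargs = (
        {"quintile": labels, "quintile_bounds": bounds}
        if k == 5
        else {"tertile": labels, "tertile_bounds": bounds}
    )
    return replace(grs, **kwargs)


def subset_one_per_gene(panel: SnpPanel, keep: dict[str, str]) -> SnpPanel:
    """Reduce to one SNP per gene, carrying weights over unchanged.

    ``keep`` maps each multi-SNP gene to the rsid to retain; single-SNP genes
    are kept as-is.
    """
    t = panel.table
    for gene, rsid in keep.items():
        if rsid not in set(t.loc[t["gene"] == gene, "rsid"]):
            raise PanelError(f"keep names rsid {rsid} which is not a {gene} SNP in the panel")
    counts = t["gene"].value_counts()
    multi = set(counts[counts > 1].index)
    uncovered = multi - set(keep)
    if uncovered:
        raise PanelError(f"keep does not cover multi-SNP genes: {sorted(uncovered)}")
    mask = t.apply(
        lambda row: counts[row["gene"]] == 1 or keep[row["gene"]] == row["rsid"], axis=1
    )
    return SnpPanel(t[mask].reset_index(drop=True))
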