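"""Allele assignment of reads in a hybrid cross via per-read SNP accounting.

Each read is summarized by the known SNP sites it covers: sites matching the
maternal allele, sites matching the paternal allele, and sites where the read
shows a deletion/N (uninformative against an N-masked reference). The
indicator statistic is

    (n_mat - n_pat - n_del) / n_total

with n_total the number of covered known SNP sites; bases matching neither
parental allele count toward n_total only, diluting the indicator. Rules, in
order: reads with more than 2 N-deletions at SNP sites are excluded; reads
covering no SNP site are unassigned; indicator > 0.5 is maternal, < -0.5 is
paternal; anything else is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DELETION_MARKS = {"DEL", "-", "N", "*"}

MATERNAL = "maternal"
PATERNAL = "paternal"
AMBIGUOUS = "ambiguous"
EXCLUDED = "excluded"
UNASSIGNED = "unassigned"

CALLS = (MATERNAL, PATERNAL, AMBIGUOUS, EXCLUDED, UNASSIGNED)


class SnpTable:
    """Biallelic SNPs of a two-strain cross: position plus parental bases."""

    def __init__(self, snps: pd.DataFrame):
        required = ["chrom", "pos", "maternal", "paternal"]
        missing = [c for c in required if c not in snps.columns]
        if missing:
            raise ValueError(f"SNP table missing columns {missing}")
        df = snps[required].copy()
        if (df["maternal"] == df["paternal"]).any():
            raise ValueError("maternal and paternal alleles must differ at every SNP")
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate SNP positions")
        self.df = df
        self._lookup = {
            (c, int(p)): (m, f)
            for c, p, m, f in zip(df["chrom"], df["pos"], df["maternal"], df["paternal"])
        }

    def __len__(self) -> int:
        return len(self.df)

    def alleles_at(self, chrom: str, pos: int):
        """(maternal, paternal) bases, or None if the site is not a known SNP."""
        return self._lookup.get((chrom, pos))

    def swapped(self) -> "SnpTable":
        df = self.df.rename(columns={"maternal": "paternal", "paternal": "maternal"})
        return SnpTable(df)


@dataclass(frozen=True)
class ReadSNPProfile:
    """Per-read tallies over covered known SNP sites."""

    read_id: str
    n_mat: int
    n_pat: int
    n_del: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_mat, self.n_pat, self.n_del, self.n_total) < 0:
            raise ValueError("profile counts must be non-negative")
        if self.n_mat + self.n_pat + self.n_del > self.n_total:
            raise ValueError("n_mat + n_pat + n_del exceeds n_total")


@dataclass(frozen=True)
class AlleleCall:
    read_id: str
    indicator: float | None
    call: str


def profile_read(observations, snps: SnpTable, read_id: str = "") -> ReadSNPProfile:
    """Tally one read's base calls at known SNP sites.

    ``observations`` is an iterable of (chrom, pos, base); positions that are
    not known SNPs are ignored. A base in ``DELETION_MARKS`` counts as an
    N-deletion; a base matching neither parental allele counts only toward
    n_total.
    """
    n_mat = n_pat = n_del = n_total = 0
    for chrom, pos, base in observations:
        alleles = snps.alleles_at(chrom, int(pos))
        if alleles is None:
            continue
        n_total += 1
        base = str(base).upper()
        if base in DELETION_MARKS:
            n_del += 1
        elif base == alleles[0]:
            n_mat += 1
        elif base == alleles[1]:
            n_pat += 1
    return ReadSNPProfile(read_id, n_mat, n_pat, n_del, n_total)


def allele_indicator(profile: ReadSNPProfile) -> float:
    """(n_mat - n_pat - n_del) / n_total; undefined when no SNP is covered."""
    if profile.n_total == 0:
        raise ValueError("indicator undefined: read covers no known SNP site")
    return (profile.n_mat - profile.n_pat - profile.n_del) / profile.n_total


def assign_allele(
    profile: ReadSNPProfile,
    indicator_cut: float = 0.5,
    max_n_del: int = 2,
) -> AlleleCall:
    """Apply the exclusion and indicator rules to one read profile."""
    if profile.n_del > max_n_del:
        return AlleleCall(profile.read_id, None, EXCLUDED)
    if profile.n_total == 0:
        return AlleleCall(profile.read_id, None, UNASSIGNED)
    ind = allele_indicator(profile)
    if ind > indicator_cut:
        return AlleleCall(profile.read_id, ind, MATERNAL)
    if ind < -indicator_cut:
        return AlleleCall(profile.read_id, ind, PATERNAL)
    return AlleleCall(profile.read_id, ind, AMBIGUOUS)


def split_reads(
    observations: pd.DataFrame,
    snps: SnpTable,
    indicator_cut: float = 0.5,
    max_n_del: int = 2,
    read_ids=None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign every read; returns the per-read call table and summary counts.

    ``observations`` has columns read_id, chrom, pos, base. ``read_ids``
    optionally lists reads with no observations at all (they come out
    unassigned); by default reads are those present in the table.
    """
    calls = []
    seen = set()
    for read_id, grp in observations.groupby("read_id", sort=True):
        seen.add(read_id)
        prof = profile_read(
            zip(grp["chrom"], grp["pos"], grp["base"]), snps, read_id=str(read_id)
        )
        calls.append(assign_allele(prof, indicator_cut, max_n_del))
    if read_ids is not None:
        for rid in read_ids:
            if rid not in seen:
                calls.append(AlleleCall(str(rid), None, UNASSIGNED))
    table = pd.DataFrame(
        [{"read_id": c.read_id, "indicator": c.indicator, "call": c.call} for c in calls],
        columns=["read_id", "indicator", "call"],
    ).sort_values("read_id", ignore_index=True)
    summary = {name: int((table["call"] == name).sum()) for name in CALLS}
    summary["total"] = len(table)
    return table, summary
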