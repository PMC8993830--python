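"""GWAS summary statistics: containers, I/O, instrument selection and allele harmonisation.

Per-variant association records (effect allele, beta, SE, p, N) are the
universal currency of summary-level Mendelian randomization.  This module
provides a validated tabular container (:class:`SummaryStats`), a reader and
writer for a simple tab-separated dialect, genome-wide-significance
instrument selection with greedy LD clumping, and allele harmonisation of
an exposure's instruments against an outcome GWAS, including the
frequency-based treatment of palindromic (A/T, C/G) variants.

Coordinates are 1-based and never enter any computation: clumping consults
an :class:`LDInfo` r-squared map only, so no genome build is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

#: Canonical column order of the tab-separated summary-statistics dialect.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]

#: Default genome-wide significance threshold for instrument selection.
GWAS_P_THRESHOLD = 5e-8
#: Default clumping threshold: retained instruments must be near-independent.
CLUMP_R2 = 0.001
#: Default half-width of the allele-frequency window around 0.5 inside which
#: a palindromic SNP is considered unresolvable and dropped.
PALINDROME_EAF_WINDOW = 0.08

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_BASES = frozenset("ACGT")


def is_palindromic(ea: str, oa: str) -> bool:
    """True for strand-ambiguous single-base pairs (A/T or C/G)."""
    return len(ea) == 1 and len(oa) == 1 and _COMPLEMENT.get(ea) == oa


def _valid_allele(a) -> bool:
    return isinstance(a, str) and len(a) > 0 and set(a) <= _VALID_BASES


@dataclass
class SummaryStats:
    """One trait's per-SNP GWAS summary statistics.

    ``table`` holds the canonical columns (see :data:`CANONICAL_COLUMNS`);
    ``EAF``, ``N``, ``CHR`` and ``POS`` may be missing (NA).  Betas are per
    effect-allele copy: SD units for quantitative traits, log-odds for
    binary traits.
    """

    trait_name: str
    table: pd.DataFrame
    trait_type: str = "quantitative"
    unit: str = "SD"
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        t = self.table.copy()
        for col in CANONICAL_COLUMNS:
            if col not in t.columns:
                t[col] = np.nan
        self.table = t[CANONICAL_COLUMNS].reset_index(drop=True)

    @property
    def scale(self) -> str:
        return "log_odds" if self.trait_type == "binary" else "linear"

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)

    def record(self, snp_id: str) -> pd.Series:
        rows = self.table[self.table["SNP"] == snp_id]
        if rows.empty:
            raise KeyError(snp_id)
        return rows.iloc[0]

    def subset(self, snp_ids) -> "SummaryStats":
        keep = self.table[self.table["SNP"].isin(set(snp_ids))].reset_index(drop=True)
        return SummaryStats(self.trait_name, keep, self.trait_type, self.unit)


def validate_records(table: pd.DataFrame):
    """Split a raw table into (valid rows, [(snp_id, reason), ...]).

    Enforces: SE > 0, p in (0, 1], EAF in (0, 1) when present, valid
    distinct alleles over {A,C,G,T}, unique SNP ids, finite beta.
    """
    t = table.copy()
    for col in ("BETA", "SE", "P", "EAF", "N"):
        if col in t.columns:
            t[col] = pd.to_numeric(t[col], errors="coerce")
    dropped = []
    reasons = pd.Series("", index=t.index, dtype=object)

    def flag(mask, reason):
        new = mask & (reasons == "")
        reasons[new] = reason

    snp = t["SNP"].astype(str)
    flag(t["BETA"].isna() | t["SE"].isna() | t["P"].isna() | snp.isin(["", "nan"]),
         "missing_value")
    flag(~(t["SE"] > 0), "nonpositive_se")
    flag(~((t["P"] > 0) & (t["P"] <= 1)), "invalid_pval")
    if "EAF" in t.columns:
        bad_eaf = t["EAF"].notna() & ~((t["EAF"] > 0) & (t["EAF"] < 1))
        flag(bad_eaf, "invalid_eaf")
    ok_alleles = t.apply(
        lambda r: _valid_allele(r["EA"]) and _valid_allele(r["OA"]) and r["EA"] != r["OA"],
        axis=1,
    ) if len(t) else pd.Series(dtype=bool)
    flag(~ok_alleles, "invalid_alleles")
    flag(snp.duplicated(keep="first"), "duplicate_snp")

    bad = reasons != ""
    for sid, why in zip(snp[bad], reasons[bad]):
        dropped.append((sid, why))
    return t[~bad].reset_index(drop=True), dropped


def read_summary_stats(path, column_map=None, trait_name=None,
                       trait_type="quantitative", unit="SD", sep="\t") -> SummaryStats:
    """Read delimited summary statistics into a validated :class:`SummaryStats`.

    ``column_map`` maps canonical field names to the source file's header
    names (e.g. ``{"P": "pvalue"}``); unmapped canonical names are taken
    verbatim.  Rows failing the record invariants are dropped and recorded
    in ``.dropped`` with a reason.
    """
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty summary-statistics file") from exc
    if raw.empty:
        raise FormatError(f"{path}: no data rows")
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing_src = [s for s in rename if s not in raw.columns]
        if missing_src:
            raise FormatError(f"{path}: mapped columns not found: {missing_src}")
        raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    table, dropped = validate_records(raw)
    if "POS" in table.columns:
        table["POS"] = pd.to_numeric(table["POS"], errors="coerce").astype("Int64")
    if "N" in table.columns:
        table["N"] = pd.to_numeric(table["N"], errors="coerce").round().astype("Int64")
    name = trait_name if trait_name is not None else str(path)
    return SummaryStats(name, table, trait_type, unit, dropped=dropped)


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write the canonical tab-separated dialect (header ``SNP CHR POS EA OA EAF BETA SE P N``)."""
    t = stats.table.copy()
    if "POS" in t.columns:
        t["POS"] = pd.to_numeric(t["POS"], errors="coerce").astype("Int64")
    if "N" in t.columns:
        t["N"] = pd.to_numeric(t["N"], errors="coerce").round().astype("Int64")
    t.to_csv(path, sep="\t", index=False, na_rep="NA")


class LDInfo:
    """Sparse symmetric map of pairwise LD r-squared between SNPs.

    Absent pairs mean *unknown*; clumping treats unknown as independent
    (r-squared 0), matching a post-clumping analysis state where synthetic
    variants are simulated unlinked.
    """

    def __init__(self, r2_map=None):
        self._r2 = {}
        if r2_map:
            for (a, b), v in dict(r2_map).items():
                v = float(v)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {v}")
                self._r2[frozenset((a, b))] = v

    def r2(self, a: str, b: str):
        """Known r-squared for the unordered pair, 1.0 on the diagonal, None if unknown."""
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)))


def select_instruments(stats: SummaryStats, p_threshold: float = GWAS_P_THRESHOLD,
                       clump_r2: float = CLUMP_R2, ld: LDInfo | None = None) -> SummaryStats:
    """Genome-wide-significant, LD-clumped instruments.

    Keeps SNPs with ``p < p_threshold`` then clumps greedily: SNPs are
    visited in ascending p order and retained only if their r-squared with
    every already-retained SNP is below ``clump_r2`` (unknown pairs count
    as independent).  Output is invariant to input row order (p ties break
    on SNP id).
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0,1)")
    if not 0 <= clump_r2 <= 1:
        raise ValueError("clump_r2 must be in [0,1]")
    t = stats.table
    sig = t[t["P"] < p_threshold].sort_values(["P", "SNP"], kind="mergesort")
    if ld is None:
        kept = list(sig["SNP"])
    else:
        kept = []
        for sid in sig["SNP"]:
            independent = True
            for other in kept:
                r2 = ld.r2(sid, other)
                if r2 is not None and r2 >= clump_r2:
                    independent = False
                    break
            if independent:
                kept.append(sid)
    keep_tab = sig[sig["SNP"].isin(kept)].sort_values(["P", "SNP"], kind="mergesort")
    return SummaryStats(stats.trait_name, keep_tab.reset_index(drop=True),
                        stats.trait_type, stats.unit)


def align_record(ref_ea, ref_oa, ref_eaf, ea, oa, beta, eaf,
                 palindrome_eaf_window=PALINDROME_EAF_WINDOW):
    """Align one record's effect allele to a reference orientation.

    Returns ``(beta, eaf, reason)`` where ``reason`` is None on success.
    Matching alleles pass through; swapped alleles negate beta and
    complement the frequency.  Palindromic variants are then checked by
    frequency: if either frequency is missing or inside the window around
    0.5 the record is unresolvable ("ambiguous_palindrome"); if the two
    frequencies fall on opposite sides of 0.5 the strands disagree and the
    beta is negated (frequency complemented).
    """
    if (ea, oa) == (ref_ea, ref_oa):
        pass
    elif (ea, oa) == (ref_oa, ref_ea):
        beta = -beta
        eaf = 1.0 - eaf if eaf is not None and np.isfinite(eaf) else np.nan
    else:
        return None, None, "allele_mismatch"
    if is_palindromic(ref_ea, ref_oa):
        w = palindrome_eaf_window
        if (ref_eaf is None or not np.isfinite(ref_eaf)
                or eaf is None or not np.isfinite(eaf)
                or abs(ref_eaf - 0.5) <= w or abs(eaf - 0.5) <= w):
            return None, None, "ambiguous_palindrome"
        if (ref_eaf < 0.5) != (eaf < 0.5):
            beta = -beta
            eaf = 1.0 - eaf
    return beta, eaf, None


@dataclass
class HarmonisedSet:
    """Allele-aligned per-SNP effect pairs for one exposure against one outcome."""

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame  # snp_id, ea, oa, bx, se_x, by, se_y, eaf_exposure, eaf_outcome
    dropped: list = field(default_factory=list)
    outcome_scale: str = "linear"

    _COLS = ["snp_id", "ea", "oa", "bx", "se_x", "by", "se_y",
             "eaf_exposure", "eaf_outcome"]

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self):
        return self.table["snp_id"].to_numpy()

    @property
    def bx(self):
        return self.table["bx"].to_numpy(float)

    @property
    def se_x(self):
        return self.table["se_x"].to_numpy(float)

    @property
    def by(self):
        return self.table["by"].to_numpy(float)

    @property
    def se_y(self):
        return self.table["se_y"].to_numpy(float)

    @classmethod
    def from_arrays(cls, bx, by, se_y, se_x=None, snp_ids=None,
                    exposure_name="exposure", outcome_name="outcome",
                    outcome_scale="linear") -> "HarmonisedSet":
        """Build directly from effect arrays (fixtures, simulations)."""
        bx = np.asarray(bx, float)
        by = np.asarray(by, float)
        se_y = np.asarray(se_y, float)
        se_x = np.zeros_like(bx) if se_x is None else np.asarray(se_x, float)
        if snp_ids is None:
            snp_ids = [f"snp{i}" for i in range(len(bx))]
        t = pd.DataFrame({
            "snp_id": list(snp_ids), "ea": "A", "oa": "G",
            "bx": bx, "se_x": se_x, "by": by, "se_y": se_y,
            "eaf_exposure": np.nan, "eaf_outcome": np.nan,
        })
        return cls(exposure_name, outcome_name, t, outcome_scale=outcome_scale)

    def drop_snp(self, snp_id) -> "HarmonisedSet":
        t = self.table[self.table["snp_id"] != snp_id].reset_index(drop=True)
        return HarmonisedSet(self.exposure_name, self.outcome_name, t,
                             outcome_scale=self.outcome_scale)

    def aligned_outcome_stats(self) -> SummaryStats:
        """Outcome records re-expressed in the exposure's allele frame."""
        t = pd.DataFrame({
            "SNP": self.table["snp_id"], "EA": self.table["ea"], "OA": self.table["oa"],
            "EAF": self.table["eaf_outcome"], "BETA": self.table["by"],
            "SE": self.table["se_y"],
            "P": 1.0,  # placeholder; p-values are not used downstream of harmonisation
        })
        trait_type = "binary" if self.outcome_scale == "log_odds" else "quantitative"
        return SummaryStats(self.outcome_name, t, trait_type)


def harmonise(exposure: SummaryStats, outcome: SummaryStats,
              palindrome_eaf_window: float = PALINDROME_EAF_WINDOW) -> HarmonisedSet:
    """Align outcome records to the exposure instruments' effect alleles.

    SNPs absent from the outcome are dropped ("missing_in_outcome");
    allele mismatches and unresolvable palindromes are dropped with their
    reason.  Harmonising an already-harmonised pair is a no-op.
    """
    if not 0 <= palindrome_eaf_window < 0.5:
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    out_by_snp = {r.SNP: r for r in outcome.table.itertuples()}
    rows, dropped = [], []
    for r in exposure.table.itertuples():
        o = out_by_snp.get(r.SNP)
        if o is None:
            dropped.append((r.SNP, "missing_in_outcome"))
            continue
        ref_eaf = r.EAF if r.EAF is not None else np.nan
        by, eaf_out, reason = align_record(
            r.EA, r.OA, ref_eaf, o.EA, o.OA, float(o.BETA),
            float(o.EAF) if o.EAF is not None and pd.notna(o.EAF) else np.nan,
            palindrome_eaf_window,
        )
        if reason is not None:
            dropped.append((r.SNP, reason))
            continue
        rows.append((r.SNP, r.EA, r.OA, float(r.BETA), float(r.SE),
                     by, float(o.SE), ref_eaf, eaf_out))
    table = pd.DataFrame(rows, columns=HarmonisedSet._COLS)
    return HarmonisedSet(exposure.trait_name, outcome.trait_name, table,
                         dropped=dropped, outcome_scale=outcome.scale)
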