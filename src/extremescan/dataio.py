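"""Readers, writers and allele harmonization.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere except BED interchange
  (0-based half-open), converted at the boundary.
* A ``GenotypeMatrix`` counts the ``a1`` allele: dosage 2 means two copies of
  ``a1``.  Missing dosages are ``numpy.nan``, never a sentinel inside [0, 2].
* Summary statistics are a :class:`pandas.DataFrame` with canonical columns
  ``chrom, pos, id, effect_allele, other_allele, beta, se, p, freq, n``;
  ``beta`` is on the log-odds scale (an OR column is converted on read).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUMSTAT_COLUMNS = [
    "chrom", "pos", "id", "effect_allele", "other_allele", "beta", "se", "p", "freq", "n",
]

#: complementary-allele pairs that cannot be oriented without strand information
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    sample_ids
        Sample identifiers, one per row of ``dosage``.
    variants
        DataFrame with at least ``chrom, pos, id, a1, a2``; ``pos`` is 1-based.
        Extra columns (e.g. true simulation frequency, LD-block id) ride along.
    dosage
        ``(n_samples, n_variants)`` array of ``a1``-allele dosages in [0, 2];
        missing entries are NaN.
    build_label
        Free-text genome build tag (default GRCh37).
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    build_label: str = "GRCh37"

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float32)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise ValueError(f"{int(bad)} dosage entries outside [0, 2]")
        v = self.variants
        for chrom, sub in v.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"variant positions not sorted on chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.variants.copy(),
            self.dosage[idx, :],
            self.build_label,
        )

    def take_variants(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosage[:, idx],
            self.build_label,
        )

    def allele_freq(self) -> np.ndarray:
        """Empirical a1 frequency per variant over non-missing samples."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0


@dataclass
class HarmonizedPair:
    """Match between summary statistics and a cohort's variants.

    ``ss_idx[k]`` (row of the summary-stat frame) pairs with cohort variant
    ``g_idx[k]``; ``sign_flip[k]`` is True when the summary-stat effect allele
    is the cohort's ``a2`` so the effect sign must be reversed.  ``dropped``
    lists unmatched summary-stat rows with a reason code in
    {allele_mismatch, ambiguous_strand, duplicate, missing_in_cohort}.
    """

    ss_idx: np.ndarray
    g_idx: np.ndarray
    sign_flip: np.ndarray
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["ss_idx", "reason"]))

    def __len__(self) -> int:
        return len(self.ss_idx)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

#: smallest p we keep after clamping a printed "0"
P_CLAMP = 1e-300

_DEFAULT_COLMAP = {
    "chrom": ["chrom", "chr", "chromosome", "#chrom"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "id": ["id", "snp", "rsid", "variant_id", "markername"],
    "effect_allele": ["effect_allele", "a1", "ea", "allele1"],
    "other_allele": ["other_allele", "a2", "oa", "allele2", "non_effect_allele"],
    "beta": ["beta", "b", "effect"],
    "or": ["or", "odds_ratio"],
    "se": ["se", "standard_error", "stderr"],
    "p": ["p", "pval", "p_value", "pvalue"],
    "freq": ["freq", "eaf", "af", "effect_allele_frequency", "maf"],
    "n": ["n", "neff", "sample_size", "nsum"],
}


def read_sumstats(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read base-GWAS summary statistics from a TSV.

    Column names are resolved case-insensitively through common synonyms or an
    explicit ``column_map`` (canonical name -> file column).  An ``or`` column
    is converted to ``beta = ln(OR)``.  ``p == 0`` is clamped to the smallest
    representable positive value and flagged in the ``p_clamped`` column; rows
    whose mandatory numeric fields fail to parse are dropped (count logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in df.columns}

    def resolve(canon: str) -> str | None:
        if column_map and canon in column_map:
            return column_map[canon]
        for cand in _DEFAULT_COLMAP[canon]:
            if cand in lower:
                return lower[cand]
        return None

    cols: dict[str, str | None] = {k: resolve(k) for k in _DEFAULT_COLMAP}
    missing = [k for k in ("chrom", "pos", "effect_allele", "other_allele", "p") if cols[k] is None]
    if missing:
        raise ValueError(f"summary statistics missing mandatory columns: {missing}")
    if cols["beta"] is None and cols["or"] is None:
        raise ValueError("summary statistics need a beta or an OR column")

    out = pd.DataFrame()
    out["chrom"] = df[cols["chrom"]].astype(str)
    out["pos"] = pd.to_numeric(df[cols["pos"]], errors="coerce")
    out["id"] = df[cols["id"]] if cols["id"] else (
        out["chrom"] + ":" + df[cols["pos"]].astype(str)
    )
    out["effect_allele"] = df[cols["effect_allele"]].str.upper()
    out["other_allele"] = df[cols["other_allele"]].str.upper()
    if cols["beta"] is not None:
        out["beta"] = pd.to_numeric(df[cols["beta"]], errors="coerce")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["beta"] = np.log(pd.to_numeric(df[cols["or"]], errors="coerce"))
    out["se"] = pd.to_numeric(df[cols["se"]], errors="coerce") if cols["se"] else np.nan
    out["p"] = pd.to_numeric(df[cols["p"]], errors="coerce").astype(float)
    out["freq"] = pd.to_numeric(df[cols["freq"]], errors="coerce") if cols["freq"] else np.nan
    out["n"] = pd.to_numeric(df[cols["n"]], errors="coerce") if cols["n"] else np.nan

    out["p_clamped"] = out["p"] == 0
    out.loc[out["p_clamped"], "p"] = P_CLAMP

    ok = out["pos"].notna() & out["beta"].notna() & out["p"].notna()
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropped %d summary-stat rows with unparseable numerics", n_bad)
    out = out[ok].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    return out


def write_sumstats(ss: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMSTAT_COLUMNS if c in ss.columns]
    ss.to_csv(path, sep="\t", index=False, columns=cols, na_rep="NA")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    keep_samples: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read cohort genotypes from a VCF (GT and/or DS) or a dosage TSV.

    The DS (dosage) FORMAT field takes precedence over GT when both are
    present.  ``keep_samples`` restricts (and orders) the sample set; any
    requested sample absent from the file is an error.
    """
    if format == "vcf":
        G = _read_vcf(path)
    elif format == "dosage_tsv":
        G = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if keep_samples is not None:
        index = {s: i for i, s in enumerate(G.sample_ids)}
        missing = [s for s in keep_samples if s not in index]
        if missing:
            raise ValueError(f"samples in keep-list absent from file: {missing}")
        G = G.take_samples([index[s] for s in keep_samples])
    return G


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append(
            dict(chrom=str(var.CHROM), pos=int(var.POS), id=var.ID or f"{var.CHROM}:{var.POS}",
                 a1=alt, a2=var.REF)
        )
        ds = var.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=np.float32).reshape(-1)
            d[d < 0] = np.nan  # cyvcf2 encodes missing as negative fill
        else:
            d = np.full(len(samples), np.nan, dtype=np.float32)
            for i, gt in enumerate(var.genotypes):
                alleles = gt[:-1]
                if all(a >= 0 for a in alleles):
                    d[i] = float(sum(1 for a in alleles if a > 0))
        dosages.append(d)
    vcf.close()
    variants = pd.DataFrame(rows)
    dosage = np.stack(dosages, axis=1) if dosages else np.empty((len(samples), 0), np.float32)
    return GenotypeMatrix(samples, variants, dosage)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF 4.2 with GT (rounded dosage) and DS (the dosage itself).

    The effect allele ``a1`` is emitted as ALT so that the ALT dosage in DS
    matches the in-memory dosage.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=extremescan\n##reference={G.build_label}\n")
        for chrom in pd.unique(G.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.sample_ids) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(G.variants.itertuples(index=False)):
            col = G.dosage[:, j]
            fields = []
            for d in col:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(float(d)))]}:{float(d):g}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.a2}\t{v.a1}\t.\t.\t.\tGT:DS\t" + "\t".join(fields) + "\n"
            )


def _read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "id", "a1", "a2"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    dosage = df[sample_ids].to_numpy(dtype=np.float32).T
    return GenotypeMatrix(sample_ids, variants, dosage)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = G.variants[["chrom", "pos", "id", "a1", "a2"]].copy()
    for i, s in enumerate(G.sample_ids):
        df[s] = G.dosage[i, :]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(
    ss: pd.DataFrame, G: GenotypeMatrix, drop_ambiguous: bool = True
) -> HarmonizedPair:
    """Match summary-stat rows to cohort variants on (chrom, pos) and alleles.

    If the summary-stat (effect, other) alleles equal the cohort (a1, a2) the
    match is direct; if they equal (a2, a1) the effect sign must flip.  A/T and
    C/G pairs are strand-ambiguous and dropped when ``drop_ambiguous`` (the
    default — no strand flipping is ever attempted).  Duplicate positions and
    allele mismatches are dropped with reason codes.  Zero matches raises
    (the usual cause is a genome-build mismatch).
    """
    if len(ss) == 0 or G.n_variants == 0:
        raise ValueError("harmonize_alleles: empty input")
    cohort = {}
    for j, v in enumerate(G.variants.itertuples(index=False)):
        cohort.setdefault((str(v.chrom), int(v.pos)), []).append(j)

    seen: set[tuple[str, int]] = set()
    ss_idx, g_idx, flips, dropped = [], [], [], []
    for i, r in enumerate(ss.itertuples(index=False)):
        key = (str(r.chrom), int(r.pos))
        if key in seen:
            dropped.append((i, "duplicate"))
            continue
        seen.add(key)
        js = cohort.get(key)
        if not js:
            dropped.append((i, "missing_in_cohort"))
            continue
        if len(js) > 1:
            dropped.append((i, "duplicate"))
            continue
        j = js[0]
        ea, oa = r.effect_allele, r.other_allele
        if drop_ambiguous and (ea, oa) in AMBIGUOUS_PAIRS:
            dropped.append((i, "ambiguous_strand"))
            continue
        a1, a2 = G.variants["a1"].iat[j], G.variants["a2"].iat[j]
        if (ea, oa) == (a1, a2):
            flip = False
        elif (ea, oa) == (a2, a1):
            flip = True
        else:
            dropped.append((i, "allele_mismatch"))
            continue
        ss_idx.append(i)
        g_idx.append(j)
        flips.append(flip)

    if not ss_idx:
        raise ValueError("no variants matched between summary statistics and cohort (build mismatch?)")
    return HarmonizedPair(
        np.asarray(ss_idx), np.asarray(g_idx), np.asarray(flips, dtype=bool),
        pd.DataFrame(dropped, columns=["ss_idx", "reason"]),
    )


def apply_harmonization(ss: pd.DataFrame, G: GenotypeMatrix, pair: HarmonizedPair) -> pd.DataFrame:
    """Summary statistics aligned to cohort orientation.

    Returns a frame indexed by cohort variant index whose ``beta`` (and
    ``freq``) are re-expressed for the cohort ``a1`` allele, so downstream
    scoring can use cohort dosages directly.
    """
    out = ss.iloc[pair.ss_idx].copy()
    out.index = pd.Index(pair.g_idx, name="g_idx")
    flip = pair.sign_flip
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    if "freq" in out.columns:
        out.loc[flip, "freq"] = 1.0 - out.loc[flip, "freq"]
    out["effect_allele"] = G.variants["a1"].to_numpy()[pair.g_idx]
    out["other_allele"] = G.variants["a2"].to_numpy()[pair.g_idx]
    # bookkeeping only: the returned betas are already cohort-oriented
    # (a live "sign_flip" column would make prscore.score flip them again)
    out["orientation_flipped"] = flip
    return out.sort_index()


# ---------------------------------------------------------------------------
# annotation formats (BED / GMT)
# ---------------------------------------------------------------------------

def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Gene annotation to BED (0-based half-open): internal 1-based inclusive
    start becomes start-1."""
    out = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start_bp"].astype(np.int64) - 1,
        "end": genes["end_bp"].astype(np.int64),
        "name": genes["id"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str},
                     names=["chrom", "start", "end", "id"], usecols=[0, 1, 2, 3])
    return pd.DataFrame({
        "id": df["id"], "chrom": df["chrom"],
        "start_bp": df["start"].astype(np.int64) + 1,
        "end_bp": df["end"].astype(np.int64),
    })


def write_gmt(catalog: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    catalog: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                catalog[parts[0]] = parts[2:]
    return catalog


# ---------------------------------------------------------------------------
# stage outputs
# ---------------------------------------------------------------------------

def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
    overwrite: bool = False,
    extra: Mapping | None = None,
) -> dict:
    """Write each table as ``<name>.tsv`` plus a JSON run-manifest.

    The manifest records a config hash, the seed and per-table row counts.
    Existing files raise unless ``overwrite`` is set.  Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "tables": {}}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        manifest["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
        manifest["config"] = {k: config[k] for k in sorted(config)}
    if extra:
        manifest.update(extra)
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        manifest["tables"][name] = {"path": path.name, "rows": int(len(table))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
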