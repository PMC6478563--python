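"""Genotype containers and quality control.

Variant QC mirrors standard array practice for family studies: drop markers
with excess missingness, markers failing the conditional exact
Hardy-Weinberg test, non-polymorphic markers and (optionally)
strand-ambiguous markers, then drop samples with excess missingness.  The
HWE test is computed across all genotyped individuals despite relatedness,
which is conservative and mirrors PLINK-style QC as applied to family cases.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "hwe_exact_test",
    "qc_filter",
    "read_ped_map",
    "read_tped",
    "read_vcf_genotypes",
    "write_ped_map",
    "write_tped",
]

MISSING = -1  # internal missing genotype code

_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


class MarkerMap:
    """Ordered biallelic marker map: chrom, id, bp (1-based), cM, alleles.

    Markers are kept in file order; bp must be strictly increasing and cM
    non-decreasing within each chromosome.
    """

    COLUMNS = ["chrom", "id", "bp", "cm", "a1", "a2"]

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"marker map missing columns {sorted(missing)}")
        self.df = df[self.COLUMNS].copy()
        self.df["bp"] = self.df["bp"].astype(np.int64)
        self.df["cm"] = self.df["cm"].astype(float)
        self.validate()

    def validate(self) -> None:
        for chrom, grp in self.df.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            cm = grp["cm"].to_numpy()
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"chrom {chrom}: bp not strictly increasing")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"chrom {chrom}: cM not non-decreasing")
            if not np.all(np.isfinite(cm)):
                raise ValueError(f"chrom {chrom}: non-finite cM")

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_slices(self) -> dict:
        """Contiguous index slice per chromosome, in map order."""
        out = {}
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.df.loc[np.asarray(keep)].reset_index(drop=True))

    def is_strand_ambiguous(self) -> np.ndarray:
        return np.array(
            [frozenset((a, b)) in _AMBIGUOUS for a, b in zip(self.df["a1"], self.df["a2"])]
        )


@dataclass
class GenotypeMatrix:
    """individuals x markers, entries in {0,1,2} counting copies of allele2;
    ``-1`` codes missing."""

    sample_ids: list[str]
    G: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.ndim != 2 or self.G.shape[0] != len(self.sample_ids):
            raise ValueError("genotype matrix shape does not match sample ids")
        bad = ~np.isin(self.G, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype entries must be in {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_markers(self) -> int:
        return self.G.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.G[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in genotype matrix") from None


# -- Hardy-Weinberg exact test ----------------------------------------------

def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Conditional exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) whose probability does not exceed
    the observed one.  Monomorphic markers have a single attainable
    configuration and return 1.0.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom1 + n_het  # copies of allele 1
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n, n_a) up to a constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln((n_b - hets) / 2 + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, n_het)]
    return float(p[p <= p_obs * (1 + 1e-12)].sum())


# -- QC filter --------------------------------------------------------------

def qc_filter(
    gm: GenotypeMatrix,
    mmap: MarkerMap,
    max_marker_missing: float = 0.05,
    hwe_alpha: float = 0.001,
    max_sample_missing: float = 0.05,
    drop_strand_ambiguous: bool = False,
) -> tuple[GenotypeMatrix, MarkerMap, dict]:
    """Apply marker filters (missingness, HWE, polymorphism/strand), then the
    sample missingness filter.  The report counts drops per filter in
    application order."""
    if gm.n_markers != mmap.n_markers:
        raise ValueError("genotype matrix and marker map sizes differ")
    G = gm.G
    miss = G == MISSING
    n = gm.n_samples

    keep = np.ones(gm.n_markers, dtype=bool)
    frac_missing = miss.mean(axis=0)
    drop_missing = frac_missing > max_marker_missing
    keep &= ~drop_missing

    hwe_fail = np.zeros(gm.n_markers, dtype=bool)
    for j in np.nonzero(keep)[0]:
        col = G[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        if n0 + n1 + n2 == 0:
            continue
        hwe_fail[j] = hwe_exact_test(n0, n1, n2) < hwe_alpha
    keep &= ~hwe_fail

    obs = ~miss
    any0 = ((G == 0) | (G == 1)).any(axis=0)
    any2 = ((G == 2) | (G == 1)).any(axis=0)
    nonpoly = ~(any0 & any2) | ~obs.any(axis=0)
    drop_nonpoly = nonpoly & keep
    keep &= ~drop_nonpoly

    if drop_strand_ambiguous:
        ambiguous = mmap.is_strand_ambiguous() & keep
    else:
        ambiguous = np.zeros(gm.n_markers, dtype=bool)
    keep &= ~ambiguous

    G2 = G[:, keep]
    if G2.shape[1] == 0:
        raise ValueError("QC removed every marker (degenerate output)")
    sample_missing = (G2 == MISSING).mean(axis=1)
    keep_samples = sample_missing <= max_sample_missing
    if not keep_samples.any():
        raise ValueError("QC removed every sample (degenerate output)")

    report = {
        "n_markers_in": gm.n_markers,
        "n_samples_in": n,
        "dropped_marker_missing": int(drop_missing.sum()),
        "dropped_hwe": int(hwe_fail.sum()),
        "dropped_nonpolymorphic": int(drop_nonpoly.sum()),
        "dropped_strand_ambiguous": int(ambiguous.sum()),
        "dropped_sample_missing": int((~keep_samples).sum()),
        "n_markers_out": int(keep.sum()),
        "n_samples_out": int(keep_samples.sum()),
    }
    gm_out = GenotypeMatrix(
        [s for s, k in zip(gm.sample_ids, keep_samples) if k],
        G2[keep_samples],
    )
    return gm_out, mmap.subset(keep), report


def qc_report_frame(report: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [{"filter": k, "count": v} for k, v in report.items()]
    )


# -- PLINK text dialects ----------------------------------------------------

def _read_map_file(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            rows.append(
                {"chrom": f[0], "id": f[1], "cm": float(f[2]), "bp": int(f[3])}
            )
    return pd.DataFrame(rows)


def _alleles_to_codes(a_pairs: np.ndarray, known=None) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Map per-marker allele-pair strings to 0/1/2 counts of allele2.

    allele1/allele2 come from ``known`` when provided, else they are the
    lexicographically smaller/larger observed allele; '0' codes missing.
    """
    n, m2 = a_pairs.shape
    m = m2 // 2
    codes = np.full((n, m), MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    for j in range(m):
        a = a_pairs[:, 2 * j]
        b = a_pairs[:, 2 * j + 1]
        obs = np.unique(np.concatenate([a, b]))
        obs = [x for x in obs if x != "0"]
        if known is not None:
            a1, a2 = known[j]
            extra = set(obs) - {a1, a2}
            if extra:
                raise ValueError(
                    f"marker column {j}: calls {sorted(extra)} not among "
                    f"reference alleles {a1}/{a2}"
                )
        else:
            if len(obs) > 2:
                raise ValueError(f"marker column {j}: more than two alleles {obs}")
            a1 = obs[0] if obs else "0"
            a2 = obs[1] if len(obs) > 1 else "0"
        alleles.append((a1, a2))
        ok = (a != "0") & (b != "0")
        codes[ok, j] = (a[ok] == a2).astype(np.int8) + (b[ok] == a2).astype(np.int8)
    return codes, alleles


def read_ped_map(prefix, mmap: "MarkerMap | None" = None) -> tuple[GenotypeMatrix, MarkerMap, pd.DataFrame]:
    """Read PLINK text ``.ped``/``.map``; returns genotypes, map, and the fam
    columns as a DataFrame.

    PLINK text cannot express the allele identity of markers monomorphic in
    the sample; pass a reference ``mmap`` carrying a1/a2 to preserve the
    orientation (otherwise alleles are assigned lexicographically from the
    observed calls).
    """
    mp = _read_map_file(f"{prefix}.map")
    fam_rows, geno_rows = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            fam_rows.append(f[:6])
            geno_rows.append(f[6:])
    a_pairs = np.array(geno_rows, dtype=object)
    if a_pairs.shape[1] != 2 * len(mp):
        raise ValueError(".ped allele columns do not match .map marker count")
    known = None
    if mmap is not None:
        if mmap.n_markers != len(mp) or not np.array_equal(
            mmap.marker_ids, mp["id"].to_numpy()
        ):
            raise ValueError("reference marker map does not match the .map file")
        known = list(zip(mmap.df["a1"], mmap.df["a2"]))
    codes, alleles = _alleles_to_codes(a_pairs, known)
    mp["a1"] = [a for a, _ in alleles]
    mp["a2"] = [b for _, b in alleles]
    fam = pd.DataFrame(
        fam_rows, columns=["fid", "iid", "pat", "mat", "sex", "pheno"]
    )
    gm = GenotypeMatrix(list(fam["iid"]), codes)
    return gm, MarkerMap(mp), fam


def read_tped(prefix) -> tuple[GenotypeMatrix, MarkerMap, pd.DataFrame]:
    """Read transposed PLINK text ``.tped``/``.tfam``."""
    fam_rows = []
    with open(f"{prefix}.tfam") as fh:
        for line in fh:
            f = line.split()
            if f:
                fam_rows.append(f[:6])
    fam = pd.DataFrame(
        fam_rows, columns=["fid", "iid", "pat", "mat", "sex", "pheno"]
    )
    map_rows, cols = [], []
    with open(f"{prefix}.tped") as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            map_rows.append(
                {"chrom": f[0], "id": f[1], "cm": float(f[2]), "bp": int(f[3])}
            )
            cols.append(f[4:])
    # cols is markers x (2*samples); reorganize to samples x 2 per marker
    mcount = len(map_rows)
    n = len(fam)
    pairs = np.empty((n, 2 * mcount), dtype=object)
    for j, c in enumerate(cols):
        c = np.asarray(c, dtype=object)
        pairs[:, 2 * j] = c[0::2]
        pairs[:, 2 * j + 1] = c[1::2]
    codes, alleles = _alleles_to_codes(pairs)
    mp = pd.DataFrame(map_rows)
    mp["a1"] = [a for a, _ in alleles]
    mp["a2"] = [b for _, b in alleles]
    gm = GenotypeMatrix(list(fam["iid"]), codes)
    return gm, MarkerMap(mp), fam


def read_vcf_genotypes(path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read biallelic genotypes (GT field only) from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, codes = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # biallelic only
        rows.append(
            {
                "chrom": v.CHROM,
                "id": v.ID or f"{v.CHROM}:{v.POS}",
                "bp": v.POS,
                "cm": 0.0,
                "a1": v.REF,
                "a2": v.ALT[0],
            }
        )
        g = np.asarray(v.genotypes, dtype=object)
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, entry in enumerate(g):
            a, b = entry[0], entry[1]
            if a < 0 or b < 0:
                continue
            col[i] = a + b
        codes.append(col)
    vcf.close()
    gm = GenotypeMatrix(samples, np.array(codes, dtype=np.int8).T)
    return gm, MarkerMap(pd.DataFrame(rows))


def write_ped_map(gm: GenotypeMatrix, mmap: MarkerMap, fam: pd.DataFrame, prefix) -> None:
    with open(f"{prefix}.map", "w") as fh:
        for r in mmap.df.itertuples():
            fh.write(f"{r.chrom} {r.id} {r.cm:g} {r.bp}\n")
    a1 = mmap.df["a1"].to_numpy()
    a2 = mmap.df["a2"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, famrow in enumerate(fam.itertuples()):
            fields = [famrow.fid, famrow.iid, famrow.pat, famrow.mat,
                      str(famrow.sex), str(famrow.pheno)]
            g = gm.G[i]
            for j in range(gm.n_markers):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [a2[j] if g[j] >= 1 else a1[j],
                               a2[j] if g[j] == 2 else a1[j]]
            fh.write(" ".join(fields) + "\n")


def write_tped(gm: GenotypeMatrix, mmap: MarkerMap, fam: pd.DataFrame, prefix) -> None:
    with open(f"{prefix}.tfam", "w") as fh:
        for r in fam.itertuples():
            fh.write(f"{r.fid} {r.iid} {r.pat} {r.mat} {r.sex} {r.pheno}\n")
    a1 = mmap.df["a1"].to_numpy()
    a2 = mmap.df["a2"].to_numpy()
    with open(f"{prefix}.tped", "w") as fh:
        for j, r in enumerate(mmap.df.itertuples()):
            fields = [str(r.chrom), r.id, f"{r.cm:g}", str(r.bp)]
            for i in range(gm.n_samples):
                g = gm.G[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [a2[j] if g >= 1 else a1[j],
                               a2[j] if g == 2 else a1[j]]
            fh.write(" ".join(fields) + "\n")
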