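"""Gene-drop simulation null for shared segments.

Founders receive phased haplotypes drawn uniformly (with replacement) from a
reference panel, preserving the panel's linkage disequilibrium exactly;
haplotypes then segregate through the fixed pedigree with Haldane (no
interference) recombination, independent of case status.  Re-running the
sharing scan on each simulated genome yields a family-specific null
distribution of sharing-run lengths, from which each observed segment gets
an empirical p-value

    p = (c + 1) / (n_sims + 1)

with c the number of simulations in which a run for the same subset size (or
larger) covers the observed segment's midpoint with at least the observed
bp length.  The +1 floor avoids zero p-values from finite simulation.

Transmission draws a Poisson crossover count per chromosome with positions
uniform on the cM scale (so the recombination fraction across map distance d
Morgans is theta = (1 - exp(-2d))/2); :func:`drop_genes` simulates one
genome at a time through the documented API, and the batched null engine
runs the same process vectorized over simulations.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genoqc import GenotypeMatrix, MarkerMap
from .pedigree import Pedigree
from .sgs_core import SharedSegment, SubsetScanConfig, iter_case_subsets

__all__ = [
    "HaplotypePanel",
    "GeneticMap",
    "NullDistribution",
    "assign_founder_haplotypes",
    "drop_genes",
    "simulate_null",
    "empirical_pvalue",
]


class AlignmentError(ValueError):
    """Panel/map marker misalignment."""


@dataclass
class HaplotypePanel:
    """Phased haplotypes x markers with alleles in {0,1}."""

    H: np.ndarray  # (n_haplotypes, n_markers) int8
    marker_ids: np.ndarray

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.int8)
        self.marker_ids = np.asarray(self.marker_ids)
        if self.H.ndim != 2 or self.H.shape[1] != len(self.marker_ids):
            raise ValueError("panel shape does not match marker ids")
        if self.H.shape[0] < 1:
            raise ValueError("panel needs at least one haplotype")
        if not np.isin(self.H, [0, 1]).all():
            raise ValueError("panel alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    @property
    def n_markers(self) -> int:
        return self.H.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.H.mean(axis=0)

    def check_polymorphic(self) -> None:
        f = self.allele_frequencies()
        mono = (f == 0) | (f == 1)
        if mono.any():
            raise ValueError(f"{int(mono.sum())} monomorphic panel markers")

    def check_alignment(self, mmap: MarkerMap) -> None:
        if self.n_markers != mmap.n_markers or not np.array_equal(
            self.marker_ids, mmap.marker_ids
        ):
            raise AlignmentError("panel markers do not align with marker map")


class GeneticMap:
    """Per-chromosome cM positions for the markers of a map."""

    def __init__(self, cm_by_chrom: dict):
        self.cm_by_chrom = {
            c: np.asarray(v, dtype=float) for c, v in cm_by_chrom.items()
        }
        for c, v in self.cm_by_chrom.items():
            if not np.all(np.isfinite(v)) or not np.all(np.diff(v) >= 0):
                raise ValueError(f"chrom {c}: cM must be finite and non-decreasing")

    @classmethod
    def from_marker_map(cls, mmap: MarkerMap) -> "GeneticMap":
        return cls(
            {c: mmap.df["cm"].to_numpy()[sl] for c, sl in mmap.chrom_slices().items()}
        )

    @classmethod
    def from_recomb_table(cls, table: pd.DataFrame, mmap: MarkerMap) -> "GeneticMap":
        """Interpolate marker cM from a (chrom, pos_bp, cm) recombination map."""
        out = {}
        for c, sl in mmap.chrom_slices().items():
            sub = table[table["chrom"].astype(str) == str(c)]
            if sub.empty:
                raise ValueError(f"recombination map lacks chromosome {c}")
            bp = mmap.df["bp"].to_numpy()[sl]
            out[c] = np.interp(bp, sub["pos_bp"].to_numpy(), sub["cm"].to_numpy())
        return cls(out)

    def span_cm(self, chrom) -> float:
        v = self.cm_by_chrom[chrom]
        return float(v[-1] - v[0])


# -- founder assignment and transmission ------------------------------------

def assign_founder_haplotypes(
    ped: Pedigree, panel: HaplotypePanel, rng: np.random.Generator,
    mmap: MarkerMap | None = None,
) -> dict:
    """Each founder receives two haplotypes drawn uniformly with replacement
    from the panel, independently per founder and independent of case
    status."""
    if mmap is not None:
        panel.check_alignment(mmap)
    out = {}
    for f in ped.founders:
        idx = rng.integers(0, panel.n_haplotypes, size=2)
        out[f.id] = panel.H[idx].copy()
    return out


def _gamete(parent_haps: np.ndarray, mmap: MarkerMap, gmap: GeneticMap,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant haplotype: Poisson(L/100) crossovers per chromosome,
    positions uniform on the cM scale (Haldane, no interference)."""
    M = parent_haps.shape[1]
    out = np.empty(M, dtype=np.int8)
    for c, sl in mmap.chrom_slices().items():
        cm = gmap.cm_by_chrom[c]
        span = cm[-1] - cm[0]
        k = rng.poisson(span / 100.0) if span > 0 else 0
        start = int(rng.integers(0, 2))
        if k:
            xpos = rng.uniform(cm[0], cm[-1], size=k)
            hap_idx = (start + np.searchsorted(np.sort(xpos), cm, side="left")) % 2
        else:
            hap_idx = np.full(sl.stop - sl.start, start)
        cols = np.arange(sl.start, sl.stop)
        out[sl] = parent_haps[hap_idx, cols]
    return out


def _topo_order(ped: Pedigree) -> list[str]:
    order, seen = [], set()

    def visit(iid):
        if iid in seen:
            return
        ind = ped.individuals[iid]
        if not ind.is_founder:
            visit(ind.father_id)
            visit(ind.mother_id)
        seen.add(iid)
        order.append(iid)

    for iid in ped.individuals:
        visit(iid)
    return order


def drop_genes(
    ped: Pedigree,
    founder_haps: dict,
    mmap: MarkerMap,
    gmap: GeneticMap,
    rng: np.random.Generator,
    output_ids=None,
) -> GenotypeMatrix:
    """Transmit founder haplotypes through the pedigree; returns genotypes
    (allele2 dosage) for ``output_ids`` (default: genotyped individuals)."""
    haps: dict[str, np.ndarray] = {k: np.asarray(v, dtype=np.int8) for k, v in founder_haps.items()}
    for iid in _topo_order(ped):
        if iid in haps:
            continue
        ind = ped.individuals[iid]
        pat = _gamete(haps[ind.father_id], mmap, gmap, rng)
        mat = _gamete(haps[ind.mother_id], mmap, gmap, rng)
        haps[iid] = np.stack([pat, mat])
    if output_ids is None:
        output_ids = [i.id for i in ped.individuals.values() if i.is_genotyped]
        if not output_ids:
            output_ids = [i.id for i in ped.genotyped_cases]
    G = np.stack([haps[i].sum(axis=0) for i in output_ids]).astype(np.int8)
    return GenotypeMatrix(list(output_ids), G)


# -- batched null simulation -------------------------------------------------

def _ancestor_closure(ped: Pedigree, ids) -> set:
    out: set = set()
    stack = list(ids)
    while stack:
        iid = stack.pop()
        if iid in out:
            continue
        out.add(iid)
        ind = ped.individuals[iid]
        if not ind.is_founder:
            stack.extend([ind.father_id, ind.mother_id])
    return out


def _gamete_states(chrom_cm, bounds, rng, B, M):
    """Parental-origin indicator (B, M) for one batch of gametes: per
    chromosome, an independent start and Poisson(L/100) crossovers with
    uniform cM positions (Haldane)."""
    S = np.zeros((B, M), dtype=np.int16)
    for ci, cm in enumerate(chrom_cm):
        lo = bounds[ci]
        span = (cm[-1] - cm[0]) / 100.0
        S[:, lo] = rng.integers(0, 2, size=B)
        if span > 0:
            k = rng.poisson(span, size=B)
            K = int(k.sum())
            if K:
                pos = rng.uniform(cm[0], cm[-1], size=K)
                b_idx = np.repeat(np.arange(B), k)
                m_idx = lo + np.searchsorted(cm, pos, side="left")
                np.add.at(S, (b_idx, m_idx), 1)
    return np.cumsum(S, axis=1, dtype=np.int16) & 1


def _drop_batch(ped, panel, chrom_cm, out_ids, rng, B, forced=None):
    """Vectorized gene drop: B simulations at once.

    ``chrom_cm`` is the list of per-chromosome marker cM arrays (map order).
    Returns int8 array (B, len(out_ids), M).  ``forced`` optionally maps
    (child_id, parent_id) -> (marker_slice, hap_index) to force a transmitted
    founder haplotype over an interval (used by the synthetic-data planter).
    Only individuals on ancestral paths of ``out_ids`` are simulated.
    """
    M = panel.n_markers
    bounds = np.cumsum([0] + [len(cm) for cm in chrom_cm])
    if bounds[-1] != M:
        raise AlignmentError("genetic map does not cover the panel markers")
    needed = _ancestor_closure(ped, out_ids)
    haps: dict[str, tuple] = {}
    for f in ped.founders:
        if f.id not in needed:
            continue
        idx = rng.integers(0, panel.n_haplotypes, size=(B, 2))
        haps[f.id] = (panel.H[idx[:, 0]], panel.H[idx[:, 1]])
    for iid in _topo_order(ped):
        if iid in haps or iid not in needed:
            continue
        ind = ped.individuals[iid]
        gametes = []
        for parent in (ind.father_id, ind.mother_id):
            hA, hB = haps[parent]
            h = _gamete_states(chrom_cm, bounds, rng, B, M)
            if forced and (iid, parent) in forced:
                sl, hap_idx = forced[(iid, parent)]
                h[:, sl] = hap_idx
            gametes.append(np.where(h == 0, hA, hB))
        haps[iid] = tuple(gametes)
    out = np.empty((B, len(out_ids), M), dtype=np.int8)
    for j, iid in enumerate(out_ids):
        hA, hB = haps[iid]
        out[:, j, :] = hA + hB
    return out


try:  # compiled scan kernel; the numpy path below is the reference fallback
    import numba as _numba

    @_numba.njit(cache=False)
    def _runs_kernel(share, bp, bounds, min_markers, size, cov2d,
                     ev_limit, ev_buf, ev_count):  # pragma: no cover
        B = share.shape[0]
        for b in range(B):
            for ci in range(bounds.shape[0] - 1):
                lo, hi = bounds[ci], bounds[ci + 1]
                run_start = -1
                for m in range(lo, hi + 1):
                    sh = share[b, m] if m < hi else False
                    if sh:
                        if run_start < 0:
                            run_start = m
                    elif run_start >= 0:
                        end = m - 1
                        L = bp[end] - bp[run_start]
                        for mm in range(run_start, end + 1):
                            if cov2d[b, mm] < L:
                                cov2d[b, mm] = L
                        if b < ev_limit and end - run_start + 1 >= min_markers:
                            c = ev_count[0]
                            if c < ev_buf.shape[0]:
                                ev_buf[c, 0] = b
                                ev_buf[c, 1] = size
                                ev_buf[c, 2] = run_start
                                ev_buf[c, 3] = end
                            ev_count[0] = c + 1
                        run_start = -1

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _runs_by_marker(share, bp):
    """Per-marker covering-run bp length for a (B, L) sharing matrix.

    Returns (runlen, left, right): runlen[b, m] = bp length of the maximal
    sharing run covering marker m (-1 where sharing fails); left/right are
    the indices of the nearest non-sharing markers (exclusive bounds).
    """
    B, L = share.shape
    idx = np.arange(L, dtype=np.int32)
    notpos = np.where(~share, idx, np.int32(-1))
    left = np.maximum.accumulate(notpos, axis=1)
    notpos2 = np.where(~share, idx, np.int32(L))
    right = np.minimum.accumulate(notpos2[:, ::-1], axis=1)[:, ::-1]
    start = np.clip(left + 1, 0, L - 1)
    end = np.clip(right - 1, 0, L - 1)
    runlen = np.where(share, bp[end] - bp[start], np.int64(-1))
    return runlen, left, right


def _scan_chunk(G, subsets_mat, ksizes, size_idx, n_sizes, bp, bounds,
                min_markers, n_ev, use_numba=None):
    """Sharing-run scan of one simulation batch.

    Returns (cov, events): ``cov[zi, b, m]`` is the maximal covering-run bp
    length at marker ``m`` among subsets with size index ``zi`` (-1 when no
    such subset shares); ``events`` holds (sim, size, start_idx, end_idx)
    rows for the first ``n_ev`` simulations.  The compiled and numpy paths
    produce identical output.
    """
    B, _, M = G.shape
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if use_numba:
        cov = np.full((n_sizes, B, M), -1, dtype=np.int64)
        is0 = np.ascontiguousarray((G == 0).transpose(1, 0, 2))  # (k, B, M)
        is2 = np.ascontiguousarray((G == 2).transpose(1, 0, 2))
        cap = max(2 * (n_ev + 1) * M, 4096)
        ev_buf = np.empty((cap, 4), dtype=np.int64)
        ev_count = np.zeros(1, dtype=np.int64)
        share = np.empty((B, M), dtype=bool)
        any0 = np.empty((B, M), dtype=bool)
        any2 = np.empty((B, M), dtype=bool)
        for si in range(subsets_mat.shape[0]):
            rows = subsets_mat[si, : ksizes[si]]
            np.copyto(any0, is0[rows[0]])
            np.copyto(any2, is2[rows[0]])
            for r in rows[1:]:
                np.logical_or(any0, is0[r], out=any0)
                np.logical_or(any2, is2[r], out=any2)
            np.logical_and(any0, any2, out=share)
            np.logical_not(share, out=share)
            before = int(ev_count[0])
            _runs_kernel(
                share, bp, bounds, min_markers, int(ksizes[si]),
                cov[size_idx[si]], n_ev, ev_buf, ev_count,
            )
            if ev_count[0] > cap:  # grow geometrically and redo this subset
                new_cap = max(2 * cap, int(ev_count[0]) + 4096)
                grown = np.empty((new_cap, 4), dtype=np.int64)
                grown[:before] = ev_buf[:before]
                ev_buf = grown
                cap = new_cap
                ev_count[0] = before
                _runs_kernel(
                    share, bp, bounds, min_markers, int(ksizes[si]),
                    cov[size_idx[si]], n_ev, ev_buf, ev_count,
                )
        return cov, ev_buf[: int(ev_count[0])].copy()
    cov = np.full((n_sizes, B, M), -1, dtype=np.int64)
    events = []
    for si in range(subsets_mat.shape[0]):
        rows = subsets_mat[si, : ksizes[si]]
        Gsub = G[:, rows, :]
        any0 = (Gsub == 0).any(axis=1)
        any2 = (Gsub == 2).any(axis=1)
        share = ~(any0 & any2)
        zi = size_idx[si]
        for ci in range(len(bounds) - 1):
            sl = slice(int(bounds[ci]), int(bounds[ci + 1]))
            share_sl = share[:, sl]
            runlen, left, right = _runs_by_marker(share_sl, bp[sl])
            ce = cov[zi][:, sl]
            np.maximum(ce, runlen, out=ce)
            if n_ev:
                sh = share_sl[:n_ev]
                startmask = sh.copy()
                startmask[:, 1:] &= ~sh[:, :-1]
                b_idx, m_start = np.nonzero(startmask)
                if b_idx.size:
                    m_end = right[:n_ev][b_idx, m_start] - 1
                    span = m_end - m_start + 1
                    ok = span >= min_markers
                    b_idx, m_start, m_end = b_idx[ok], m_start[ok], m_end[ok]
                    events.append(np.stack([
                        b_idx,
                        np.full(b_idx.size, int(ksizes[si])),
                        m_start + sl.start,
                        m_end + sl.start,
                    ], axis=1))
    ev = (
        np.concatenate(events).astype(np.int64)
        if events
        else np.empty((0, 4), dtype=np.int64)
    )
    return cov, ev


@dataclass
class NullDistribution:
    """Family-specific gene-drop null summaries.

    ``sorted_cov[s]`` has shape (n_markers, n_sims): for each marker, the
    sorted (ascending) distribution over simulations of the maximal bp
    length of a sharing run covering that marker among subsets of size >= s
    (-1 when no subset shares there).  ``events`` records the maximal runs
    (subset size, start/end/midpoint marker, bp length) observed in the
    first ``n_event_sims`` simulations, de-duplicated per simulation within
    a subset size.
    """

    family_id: str
    n_sims: int
    seed: int
    min_subset_size: int
    sizes: list
    bp: np.ndarray
    chroms: np.ndarray  # per-marker chromosome labels
    sorted_cov: dict
    events: pd.DataFrame
    n_event_sims: int
    config_hash: str = ""

    def marker_index(self, chrom, bp_pos) -> int:
        """Index of the map marker on ``chrom`` nearest to ``bp_pos``."""
        on = np.nonzero(self.chroms == chrom)[0]
        if on.size == 0:
            raise ValueError(f"chromosome {chrom!r} not covered by the null")
        return int(on[np.argmin(np.abs(self.bp[on] - bp_pos))])

    def tail_count(self, size: int, marker: int, length_bp: float) -> int:
        """Number of simulations whose covering run at ``marker`` for subset
        size >= ``size`` is at least ``length_bp``."""
        s = self._clamp_size(size)
        col = self.sorted_cov[s][marker]
        return int(self.n_sims - np.searchsorted(col, length_bp, side="left"))

    def _clamp_size(self, size: int) -> int:
        sizes = sorted(self.sorted_cov)
        if size <= sizes[0]:
            return sizes[0]
        if size in self.sorted_cov:
            return size
        below = [s for s in sizes if s <= size]
        if not below:
            return sizes[0]
        return below[-1]

    # -- persistence --------------------------------------------------------
    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        meta = {
            "family_id": self.family_id,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "min_subset_size": self.min_subset_size,
            "sizes": [int(s) for s in self.sizes],
            "n_event_sims": self.n_event_sims,
            "config_hash": self.config_hash,
        }
        with open(os.path.join(outdir, "null_meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        pd.DataFrame({"chrom": self.chroms, "bp": self.bp}).to_csv(
            os.path.join(outdir, "null_markers.tsv"), sep="\t", index=False
        )
        self.events.to_csv(
            os.path.join(outdir, "null_events.tsv"), sep="\t", index=False
        )
        for s, arr in self.sorted_cov.items():
            pd.DataFrame(arr).to_csv(
                os.path.join(outdir, f"null_cov_size{s}.tsv"),
                sep="\t", index=False, header=False,
            )

    @classmethod
    def load(cls, outdir) -> "NullDistribution":
        with open(os.path.join(outdir, "null_meta.json")) as fh:
            meta = json.load(fh)
        mk = pd.read_csv(os.path.join(outdir, "null_markers.tsv"), sep="\t")
        events = pd.read_csv(os.path.join(outdir, "null_events.tsv"), sep="\t")
        cov = {}
        for s in meta["sizes"]:
            arr = pd.read_csv(
                os.path.join(outdir, f"null_cov_size{s}.tsv"),
                sep="\t", header=None,
            ).to_numpy(dtype=np.int64)
            cov[int(s)] = arr
        return cls(
            family_id=meta["family_id"],
            n_sims=int(meta["n_sims"]),
            seed=int(meta["seed"]),
            min_subset_size=int(meta["min_subset_size"]),
            sizes=[int(s) for s in meta["sizes"]],
            bp=mk["bp"].to_numpy(),
            chroms=mk["chrom"].to_numpy(),
            sorted_cov=cov,
            events=events,
            n_event_sims=int(meta["n_event_sims"]),
            config_hash=meta.get("config_hash", ""),
        )


def _config_hash(ped, panel, cfg, n_sims, seed, case_ids, chunk_size, event_sims):
    h = hashlib.sha256()
    h.update(repr((
        ped.family_id, sorted(ped.individuals), panel.n_haplotypes,
        panel.n_markers, cfg.min_subset_size, cfg.min_markers_per_run,
        n_sims, seed, tuple(sorted(case_ids)), chunk_size, event_sims,
    )).encode())
    return h.hexdigest()[:16]


def simulate_null(
    ped: Pedigree,
    panel: HaplotypePanel,
    mmap: MarkerMap,
    gmap: GeneticMap,
    cfg: SubsetScanConfig = SubsetScanConfig(),
    n_sims: int = 10_000,
    seed: int = 0,
    case_ids=None,
    chunk_size: int = 1000,
    event_sims: int = 1500,
    checkpoint_dir=None,
    checkpoint_every: int = 1000,
) -> NullDistribution:
    """Gene-drop null for one family.

    Simulations are generated in fixed-size chunks with per-chunk RNG
    substreams spawned from ``seed``, so results are bit-identical for a
    given seed regardless of interruption or worker count.  With
    ``checkpoint_dir`` set, completed chunks are persisted and an
    interrupted run resumes where it stopped.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    panel.check_alignment(mmap)
    if case_ids is None:
        case_ids = [i.id for i in ped.genotyped_cases]
    case_ids = sorted(case_ids)
    subsets = [
        tuple(s) for s in iter_case_subsets(case_ids, cfg.min_subset_size, cfg.max_subsets)
    ]
    sizes = sorted({len(s) for s in subsets})
    max_k = max(len(s) for s in subsets)
    subsets_mat = np.zeros((len(subsets), max_k), dtype=np.int64)
    ksizes = np.array([len(s) for s in subsets], dtype=np.int64)
    for i, s in enumerate(subsets):
        subsets_mat[i, : len(s)] = [case_ids.index(m) for m in s]
    size_idx = np.array([sizes.index(len(s)) for s in subsets], dtype=np.int64)
    bp = mmap.df["bp"].to_numpy()
    slices = mmap.chrom_slices()
    chrom_cm = [gmap.cm_by_chrom[c] for c in slices]
    chrom_labels = mmap.df["chrom"].to_numpy()
    event_sims = min(event_sims, n_sims)
    chash = _config_hash(ped, panel, cfg, n_sims, seed, case_ids, chunk_size, event_sims)

    n_chunks = (n_sims + chunk_size - 1) // chunk_size
    cov_parts = {s: [] for s in sizes}
    ev_parts = []
    start_chunk = 0

    ckpt_path = None
    if checkpoint_dir is not None:
        os.makedirs(checkpoint_dir, exist_ok=True)
        ckpt_path = os.path.join(checkpoint_dir, f"null_ckpt_{chash}.npz")
        if os.path.exists(ckpt_path):
            z = np.load(ckpt_path, allow_pickle=False)
            start_chunk = int(z["n_chunks_done"])
            for s in sizes:
                arr = z[f"cov_{s}"]
                if arr.size:
                    cov_parts[s].append(arr)
            ev = z["events"]
            if ev.size:
                ev_parts.append(ev)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_chunks)
    done_since_ckpt = 0
    for ci in range(start_chunk, n_chunks):
        lo = ci * chunk_size
        B = min(chunk_size, n_sims - lo)
        rng = np.random.default_rng(child_seeds[ci])
        G = _drop_batch(ped, panel, chrom_cm, case_ids, rng, B)
        n_ev = max(0, min(event_sims - lo, B))
        bounds = np.array(
            [sl.start for sl in slices.values()] + [mmap.n_markers], dtype=np.int64
        )
        cov, ev = _scan_chunk(
            G, subsets_mat, ksizes, size_idx, len(sizes), bp, bounds,
            cfg.min_markers_per_run, n_ev,
        )
        # suffix max over sizes: coverage for "size >= s"
        for zi in range(len(sizes) - 2, -1, -1):
            np.maximum(cov[zi], cov[zi + 1], out=cov[zi])
        for zi, s in enumerate(sizes):
            cov_parts[s].append(cov[zi])
        if ev.size:
            # dedupe identical runs across same-size subsets (packed keys)
            M_ = mmap.n_markers
            key = ((ev[:, 0] * 64 + ev[:, 1]) * M_ + ev[:, 2]) * M_ + ev[:, 3]
            ev = ev[np.unique(key, return_index=True)[1]]
            ev[:, 0] += lo
            ev_parts.append(ev)
        done_since_ckpt += B
        if ckpt_path is not None and (
            done_since_ckpt >= checkpoint_every or ci == n_chunks - 1
        ):
            _write_checkpoint(ckpt_path, ci + 1, sizes, cov_parts, ev_parts)
            done_since_ckpt = 0

    cov_sorted = {}
    for s in sizes:
        arr = np.concatenate(cov_parts[s], axis=0)  # (n_sims, M)
        cov_sorted[s] = np.sort(arr.T, axis=1)  # (M, n_sims)
    if ev_parts:
        ev = np.concatenate(ev_parts)
        events = pd.DataFrame(
            ev, columns=["sim", "size", "start_idx", "end_idx"]
        )
        start = events["start_idx"].to_numpy(dtype=int)
        end = events["end_idx"].to_numpy(dtype=int)
        # anchor marker: nearest to the bp midpoint, within the run (the
        # same rule empirical_pvalue applies to observed segments)
        mid_bp = 0.5 * (bp[start] + bp[end])
        mid = np.empty(len(events), dtype=np.int64)
        for sl in slices.values():
            on = (start >= sl.start) & (start < sl.stop)
            if not on.any():
                continue
            pos = sl.start + np.searchsorted(bp[sl], mid_bp[on])
            lo_c = np.clip(pos - 1, start[on], end[on])
            hi_c = np.clip(pos, start[on], end[on])
            pick_hi = np.abs(bp[hi_c] - mid_bp[on]) < np.abs(bp[lo_c] - mid_bp[on])
            mid[np.nonzero(on)[0]] = np.where(pick_hi, hi_c, lo_c)
        events["mid_idx"] = mid
        events["length_bp"] = bp[end] - bp[start]
    else:
        events = pd.DataFrame(
            {c: pd.Series(dtype=np.int64)
             for c in ["sim", "size", "start_idx", "end_idx", "mid_idx", "length_bp"]}
        )

    return NullDistribution(
        family_id=ped.family_id,
        n_sims=n_sims,
        seed=seed,
        min_subset_size=cfg.min_subset_size,
        sizes=sizes,
        bp=bp,
        chroms=chrom_labels,
        sorted_cov=cov_sorted,
        events=events,
        n_event_sims=event_sims,
        config_hash=chash,
    )


def _write_checkpoint(path, n_chunks_done, sizes, cov_parts, ev_parts):
    payload = {"n_chunks_done": np.array(n_chunks_done)}
    for s in sizes:
        payload[f"cov_{s}"] = (
            np.concatenate(cov_parts[s], axis=0) if cov_parts[s] else np.empty((0, 0))
        )
    payload["events"] = (
        np.concatenate(ev_parts) if ev_parts else np.empty((0, 4), dtype=np.int64)
    )
    tmp = path + ".tmp.npz"
    np.savez_compressed(tmp, **payload)
    os.replace(tmp, path)


def read_panel_vcf(path, mmap: MarkerMap | None = None) -> HaplotypePanel:
    """Load a phased haplotype panel from a VCF (GT field only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, cols = [], []
    for v in vcf:
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        col = []
        for entry in v.genotypes:
            if entry[0] < 0 or entry[1] < 0:
                raise ValueError(f"panel variant {ids[-1]}: missing genotype")
            col.extend([entry[0], entry[1]])
        cols.append(col)
    vcf.close()
    panel = HaplotypePanel(
        np.asarray(cols, dtype=np.int8).T, np.asarray(ids, dtype=object)
    )
    if mmap is not None:
        panel.check_alignment(mmap)
    return panel


def empirical_pvalue(observed: SharedSegment, null: NullDistribution) -> float:
    """(c+1)/(n_sims+1) for the observed segment against the family null."""
    m = null.marker_index(observed.chromosome, observed.midpoint_bp)
    c = null.tail_count(observed.subset.size, m, observed.length_bp)
    return (c + 1) / (null.n_sims + 1)


def attach_pvalues(segments, null: NullDistribution) -> None:
    for s in segments:
        s.p_value = empirical_pvalue(s, null)
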