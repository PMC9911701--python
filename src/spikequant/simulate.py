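"""Mechanistic simulator of RNA Pol II transcription with premature
termination, and of the calibrated sequencing assays that measure it.

The model
---------
Each gene initiates polymerases at rate ``k_init`` (arbitrary units).  In a
CpG-island (CGI)-proximal *attenuation zone* downstream of the TSS, a
termination machinery (ZC3H4 level ``z``) imposes a per-bp termination
hazard that is antagonised by SET1 complexes (level ``s``) bound over the
CpG-rich region, and damped at high initiation rates (highly transcribed
genes are refractory).  The effective per-bp hazard for gene ``g`` is

    H_g = h0 * z * (1 - alpha * o_g * s) / (1 + k_init / K)

where ``o_g`` is the gene's SET1 occupancy (non-zero only at CGI genes) and
``K`` the initiation-rate saturation constant.  The probability that a
polymerase traverses the zone into productive elongation is the survival

    S_g = exp(-H_g * L_zone)

giving a productive transcriptional flux ``F_g = k_init * S_g``.  Within
the zone the hazard density follows the gene's CpG-density profile, so
nascent coverage decays across the CpG-rich region and is flat at
``k_init * S_g`` beyond it.

Steady-state mRNA abundance follows first-order decay with rate ``k_deg``:
after an acute perturbation switches the flux from F_old to F_new at t=0,

    R_g(t) = F_new / k_deg + (F_old - F_new) / k_deg * exp(-k_deg * t)

so total-RNA (cRNA-seq) responses lag nascent (cTT-seq) responses, more so
for long-lived transcripts.

Assays
------
Expected per-bin coverage and per-feature read masses are produced for
cTT-seq (nascent, flux-proportional), cRNA-seq (abundance-proportional),
Pol II cChIP-seq (promoter-proximal pause peak plus body occupancy
``flux / elongation_rate``), SET1 cChIP-seq (CpG-density-shaped, ``o_g*s``)
and H3K4me3 cChIP-seq.  Libraries are sequenced from a mixture of target
cells with ``mixing_ratio`` spike-in cells whose features have invariant
abundance; read counts are negative-binomially distributed around the
expected depth shares, and ChIP assays come with matched input libraries
that sample the cell mixture uniformly (they control for mixing, not
enrichment).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import SampleCounts
from .profiles import CoverageTrack

__all__ = [
    "GeneSpec",
    "EnhancerSpec",
    "SpikeFeature",
    "GenomeSpec",
    "ConditionSpec",
    "KineticParams",
    "ExpectationSet",
    "ConfigurationError",
    "build_genome",
    "expected_signals",
    "sample_counts",
    "sample_coverage",
    "derive_rng",
]

ASSAYS = ("cTT", "cRNA", "chip_polII", "chip_set1", "chip_h3k4me3")
CHIP_ASSAYS = ("chip_polII", "chip_set1", "chip_h3k4me3")


class ConfigurationError(ValueError):
    """Inconsistent simulator configuration (e.g. zone outside a gene)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class GeneSpec:
    """One simulated gene.

    ``tss``/``tes`` are the biological 5' and 3' positions: for a minus
    strand gene the TSS is the higher coordinate.  ``cgi`` is a
    TSS-relative interval (negative = upstream of the TSS) and
    ``cgi_density`` the per-bin CpG density over the downstream part of
    the island, peaking downstream of the TSS.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    cgi: tuple[int, int] | None = None
    cgi_density: np.ndarray | None = None
    set1_occupancy: float = 0.0
    k_init: float = 1.0
    k_deg: float = 0.2
    k_as: float = 0.1

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


@dataclass
class EnhancerSpec:
    id: str
    chrom: str
    start: int
    end: int
    k_init: float = 0.5


@dataclass
class SpikeFeature:
    id: str
    length: int
    abundance: float


@dataclass
class GenomeSpec:
    genes: list[GeneSpec]
    enhancers: list[EnhancerSpec]
    spike_features: list[SpikeFeature]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene identifiers must be unique")
        for g in self.genes:
            L = self.chrom_lengths.get(g.chrom)
            if L is None or g.start < 0 or g.end > L:
                raise ValueError(f"gene {g.id} outside chromosome bounds")
        for sf in self.spike_features:
            if sf.abundance <= 0:
                raise ValueError(f"spike feature {sf.id} has non-positive abundance")

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [g.id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "set1_occupancy": [g.set1_occupancy for g in self.genes],
                "k_init": [g.k_init for g in self.genes],
            }
        ).set_index("id", drop=False)


@dataclass
class ConditionSpec:
    """One experimental condition/library.

    ``s`` and ``z`` are the remaining SET1 and ZC3H4 protein levels
    (1 = untreated, 0 = fully depleted after dTAG treatment);
    ``t_since_depletion`` is the time since depletion in hours;
    ``mixing_ratio`` is spike-in cells per target cell (the study mixes
    one part spike cells to four parts target cells, i.e. 0.25).
    """

    label: str
    s: float = 1.0
    z: float = 1.0
    t_since_depletion: float = 2.0
    assay: str = "cTT"
    mixing_ratio: float = 0.25
    depth: float = 2e6

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.z <= 1.0):
            raise ValueError("s and z must lie in [0, 1]")
        if self.depth <= 0 or self.mixing_ratio <= 0:
            raise ValueError("depth and mixing_ratio must be positive")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass
class KineticParams:
    """Tunable model parameters.

    h0 : baseline termination hazard (1/bp) at z=1, no protection, k_init << K.
    default_zone : attenuation-zone length (bp) for genes without a CGI;
        CGI genes use TSS..CGI-3'-edge.
    alpha : SET1 protection coefficient in [0, 1].
    K : initiation-rate saturation constant (a.u.); genes with
        k_init >> K are refractory to termination.
    phi : negative-binomial dispersion of sampled counts (var = mu + phi*mu^2).
    pause_height, pause_width, pause_offset : promoter-proximal Pol II
        peak (relative amplitude, Gaussian sd in bp, centre downstream of
        TSS in bp).
    elongation_rate : converts flux to Pol II body density (a.u.).
    """

    h0: float = 1.5e-3
    default_zone: int = 1500
    alpha: float = 0.85
    K: float = 5.0
    phi: float = 0.05
    pause_height: float = 10.0
    pause_width: float = 150.0
    pause_offset: float = 100.0
    elongation_rate: float = 1.0
    antisense_length: int = 3000
    enhancer_arm: int = 1000
    unstable_lifetime_h: float = 0.25
    set1_scale: float = 5.0
    h3k4me3_scale: float = 5.0
    bin_width: int = 50

    def __post_init__(self) -> None:
        if self.h0 < 0 or self.phi < 0 or self.K <= 0:
            raise ValueError("require h0 >= 0, phi >= 0, K > 0")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class ExpectationSet:
    """Deterministic expected signals for one (genome, condition) pair."""

    condition: ConditionSpec
    kinetics: KineticParams
    genes: pd.DataFrame
    enhancers: pd.DataFrame
    target_masses: pd.Series
    spike_masses: pd.Series
    input_target_masses: pd.Series | None
    input_spike_masses: pd.Series | None
    tracks: dict[str, CoverageTrack]
    unit_track_masses: pd.Series

    def verify(self, rtol: float = 1e-6) -> None:
        """Check that per-unit coverage integrals match the analytic masses."""
        for uid, written in self.unit_track_masses.items():
            expected = self.target_masses[uid]
            if expected == 0:
                if abs(written) > 1e-12:
                    raise AssertionError(f"unit {uid}: nonzero coverage, zero mass")
            elif abs(written - expected) > rtol * expected:
                raise AssertionError(
                    f"unit {uid}: coverage integral {written} != mass {expected}"
                )

    def total_target_mass(self) -> float:
        return float(self.target_masses.sum())


# --------------------------------------------------------------------------
# genome construction
# --------------------------------------------------------------------------

def _snap(x: float, bw: int) -> int:
    return int(round(x / bw)) * bw


def build_genome(
    n_genes: int,
    n_enhancers: int | None = None,
    n_spike: int = 200,
    seed: int = 0,
    cgi_fraction: float = 0.7,
    k_init_range: tuple[float, float] = (0.1, 100.0),
    min_gene_length: int = 2000,
    halflife_median_h: float = 4.0,
    halflife_sigma: float = 0.6,
    non_cgi_weakening: float = 0.05,
    bin_width: int = 50,
    n_chroms: int = 4,
) -> GenomeSpec:
    """Draw a random genome annotation with kinetic parameters.

    Initiation rates are log-uniform over ``k_init_range`` (three orders
    of magnitude by default, so every expression decile is populated); a
    ``cgi_fraction`` of genes carry a CGI with a CpG-density profile
    peaking downstream of the TSS, and only those genes have SET1
    occupancy.  Genes without a CGI have their initiation rate scaled by
    ``non_cgi_weakening``: CGI promoters are the broadly active promoter
    class in mammalian cells, while non-CGI promoters are predominantly
    weak or tissue-specific.  All coordinates are snapped to
    ``bin_width`` so binned coverage aligns exactly with gene
    boundaries.  Deterministic for a fixed seed.
    """
    if n_genes < 1 or n_spike < 1:
        raise ValueError("counts must be >= 1")
    if n_enhancers is None:
        n_enhancers = max(1, n_genes // 5)
    if n_enhancers < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 <= cgi_fraction <= 1.0):
        raise ValueError("cgi_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x01]))
    bw = bin_width

    genes: list[GeneSpec] = []
    enh: list[EnhancerSpec] = []
    chrom_pos = {f"chr{i + 1}": 0 for i in range(n_chroms)}
    chrom_names = list(chrom_pos)

    lengths = np.maximum(
        min_gene_length, rng.uniform(4000, 16000, n_genes)
    )
    k_inits = np.exp(
        rng.uniform(np.log(k_init_range[0]), np.log(k_init_range[1]), n_genes)
    )
    halflives = np.exp(rng.normal(np.log(halflife_median_h), halflife_sigma, n_genes))
    has_cgi = rng.random(n_genes) < cgi_fraction
    strands = rng.choice(["+", "-"], n_genes)

    for i in range(n_genes):
        chrom = chrom_names[i % n_chroms]
        gap = _snap(rng.uniform(6000, 15000), bw)
        g0 = chrom_pos[chrom] + gap
        L = _snap(lengths[i], bw)
        cgi = None
        density = None
        occ = 0.0
        if has_cgi[i]:
            down = _snap(rng.uniform(1000, 2000), bw)
            down = min(down, L - bw)  # zone must sit inside the gene
            cgi = (-200, down)
            # CpG density peaks downstream of the TSS and decays to zero
            # before the island's 3' edge
            mids = (np.arange(down // bw) + 0.5) * bw
            support = 0.8 * down
            density = np.where(
                mids < support, np.sin(np.pi * mids / support) ** 2, 0.0
            )
            occ = float(rng.beta(8.0, 2.0))
        k_i = float(k_inits[i] if has_cgi[i] else k_inits[i] * non_cgi_weakening)
        strand = strands[i]
        tss = g0 if strand == "+" else g0 + L
        tes = g0 + L if strand == "+" else g0
        genes.append(
            GeneSpec(
                id=f"gene_{i:05d}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                tes=tes,
                cgi=cgi,
                cgi_density=density,
                set1_occupancy=occ,
                k_init=k_i,
                k_deg=float(np.log(2.0) / halflives[i]),
                k_as=float(k_i * rng.uniform(0.05, 0.3)),
            )
        )
        chrom_pos[chrom] = g0 + L

    for j in range(n_enhancers):
        chrom = chrom_names[j % n_chroms]
        g0 = chrom_pos[chrom] + _snap(rng.uniform(6000, 12000), bw)
        width = _snap(rng.uniform(400, 1200), bw)
        enh.append(
            EnhancerSpec(
                id=f"enh_{j:05d}",
                chrom=chrom,
                start=g0,
                end=g0 + width,
                k_init=float(np.exp(rng.uniform(np.log(0.05), np.log(5.0)))),
            )
        )
        chrom_pos[chrom] = g0 + width

    spikes = [
        SpikeFeature(
            id=f"spike_{k:04d}",
            length=int(rng.integers(20, 101) * bw),
            abundance=float(np.exp(rng.uniform(np.log(1.0), np.log(100.0)))),
        )
        for k in range(n_spike)
    ]

    chrom_lengths = {c: pos + 20000 for c, pos in chrom_pos.items()}
    return GenomeSpec(genes, enh, spikes, chrom_lengths)


# --------------------------------------------------------------------------
# expected signals
# --------------------------------------------------------------------------

def _zone_profile(gene: GeneSpec, kin: KineticParams) -> tuple[int, np.ndarray]:
    """Attenuation-zone length and per-bin hazard weights w_b.

    Weights are normalised so that sum(w_b) * bin_width == L_zone; the
    total zone hazard is then exactly H_g * L_zone regardless of shape.
    """
    bw = kin.bin_width
    if gene.cgi is not None:
        zone_len = gene.cgi[1]
        d = gene.cgi_density
        if d is None or len(d) != zone_len // bw:
            d = np.ones(zone_len // bw)
    else:
        zone_len = min(kin.default_zone, gene.length - bw)
        d = np.ones(zone_len // bw)
    if zone_len <= 0 or zone_len > gene.length:
        raise ConfigurationError(
            f"attenuation zone of gene {gene.id} falls outside the gene"
        )
    w = d * zone_len / (d.sum() * bw)
    return zone_len, w


def _survival_profile(
    k: float, H: float, zone_len: int, w: np.ndarray, bw: int
) -> tuple[np.ndarray, float]:
    """Bin-averaged coverage k*exp(-cumulative hazard) across the zone,
    plus the survival at the zone's 3' edge.  Bin values are exact
    averages of the piecewise-exponential, so the coverage integral
    matches the analytic flux integral to machine precision."""
    haz = H * w * bw  # per-bin hazard increments
    c_edges = np.concatenate([[0.0], np.cumsum(haz)])
    e = np.exp(-c_edges)
    vals = np.empty(len(w))
    nonflat = haz > 0
    vals[nonflat] = (e[:-1][nonflat] - e[1:][nonflat]) / haz[nonflat]
    vals[~nonflat] = e[:-1][~nonflat]
    return k * vals, float(e[-1])


def _hazard(kin: KineticParams, z: float, s: float, o: float, k: float) -> float:
    return kin.h0 * z * (1.0 - kin.alpha * o * s) / (1.0 + k / kin.K)


def expected_signals(
    genome: GenomeSpec,
    condition: ConditionSpec,
    kinetics: KineticParams | None = None,
) -> ExpectationSet:
    """Compute the deterministic expected signal set for one condition.

    No sampling occurs here; the returned :class:`ExpectationSet` holds
    per-gene survival/flux/abundance, per-unit read masses for the
    condition's assay, and per-strand expected coverage tracks whose
    integrals match the masses (verified on construction).
    """
    kin = kinetics or KineticParams()
    bw = kin.bin_width
    cond = condition
    s, z, t = cond.s, cond.z, cond.t_since_depletion

    tracks = {
        st: {c: np.zeros(-(-L // bw)) for c, L in genome.chrom_lengths.items()}
        for st in ("+", "-")
    }
    target_masses: dict[str, float] = {}
    written: dict[str, float] = {}
    gene_rows = []

    def paint(strand: str, chrom: str, start_bin: int, vals: np.ndarray, fwd: bool,
              uid: str) -> None:
        arr = tracks[strand][chrom]
        v = vals if fwd else vals[::-1]
        lo, hi = start_bin, start_bin + len(v)
        arr[lo:hi] += v
        written[uid] = written.get(uid, 0.0) + float(v.sum()) * bw

    for g in genome.genes:
        zone_len, w = _zone_profile(g, kin)
        H = _hazard(kin, z, s, g.set1_occupancy, g.k_init)
        H_old = _hazard(kin, 1.0, 1.0, g.set1_occupancy, g.k_init)
        zone_prof, S = _survival_profile(g.k_init, H, zone_len, w, bw)
        S_old = float(np.exp(-H_old * zone_len))
        F, F_old = g.k_init * S, g.k_init * S_old
        R = F / g.k_deg + (F_old - F) / g.k_deg * np.exp(-g.k_deg * t)

        # antisense unit: extragenic, no SET1 protection (o = 0)
        as_len = kin.antisense_length
        as_zone = min(kin.default_zone, as_len)
        H_as = _hazard(kin, z, s, 0.0, g.k_as)
        S_as = float(np.exp(-H_as * as_zone))
        H_as_old = _hazard(kin, 1.0, 1.0, 0.0, g.k_as)
        F_as = g.k_as * S_as

        fwd = g.strand == "+"
        n_gene = g.length // bw
        n_zone = zone_len // bw
        uid = g.id
        as_id = f"as:{g.id}"

        if cond.assay == "cTT":
            prof = np.concatenate([zone_prof, np.full(n_gene - n_zone, F)])
            mass = float(prof.sum()) * bw
            as_prof_zone, _ = _survival_profile(
                g.k_as, H_as, as_zone, np.ones(as_zone // bw), bw
            )
            as_prof = np.concatenate(
                [as_prof_zone, np.full((as_len - as_zone) // bw, F_as)]
            )
            as_mass = float(as_prof.sum()) * bw
        elif cond.assay == "cRNA":
            prof = np.full(n_gene, R)
            mass = R * g.length
            R_as = F_as * kin.unstable_lifetime_h
            as_prof = np.full(as_len // bw, R_as)
            as_mass = R_as * as_len
        elif cond.assay == "chip_polII":
            body = np.concatenate([zone_prof, np.full(n_gene - n_zone, F)])
            body = body / kin.elongation_rate
            amp = kin.pause_height * g.k_init / kin.elongation_rate
            edges = np.arange(n_gene + 1) * bw
            cdf = norm.cdf((edges - kin.pause_offset) / kin.pause_width)
            pause = amp * kin.pause_width * np.sqrt(2 * np.pi) * np.diff(cdf) / bw
            prof = body + pause
            mass = float(prof.sum()) * bw
            as_prof = np.full(as_len // bw, F_as / kin.elongation_rate)
            as_mass = float(as_prof.sum()) * bw
        elif cond.assay == "chip_set1":
            dens = np.zeros(n_gene)
            if g.set1_occupancy > 0:
                shape = _zone_profile(g, kin)[1]
                dens[:n_zone] = kin.set1_scale * g.set1_occupancy * s * shape
            prof = dens
            mass = float(prof.sum()) * bw
            as_prof = np.zeros(as_len // bw)
            as_mass = 0.0
        elif cond.assay == "chip_h3k4me3":
            prof = np.zeros(n_gene)
            if g.set1_occupancy > 0:
                prof[:n_zone] = kin.h3k4me3_scale * g.set1_occupancy * s
            mass = float(prof.sum()) * bw
            as_prof = np.zeros(as_len // bw)
            as_mass = 0.0
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown assay {cond.assay!r}")

        target_masses[uid] = mass
        target_masses[as_id] = as_mass
        sense_strand = "+" if fwd else "-"
        anti_strand = "-" if fwd else "+"
        start_bin = g.start // bw
        paint(sense_strand, g.chrom, start_bin, prof, fwd, uid)
        # antisense unit transcribes away from the promoter, upstream of TSS
        if fwd:
            as_start_bin = g.tss // bw - len(as_prof)
        else:
            as_start_bin = g.tss // bw
        if as_start_bin >= 0 and as_mass >= 0:
            if as_start_bin + len(as_prof) <= len(tracks[anti_strand][g.chrom]):
                paint(anti_strand, g.chrom, as_start_bin, as_prof, not fwd, as_id)
            else:
                written[as_id] = 0.0
                target_masses[as_id] = 0.0
        else:
            written[as_id] = 0.0
            target_masses[as_id] = 0.0

        gene_rows.append(
            {
                "id": g.id,
                "k_init": g.k_init,
                "o": g.set1_occupancy,
                "length": g.length,
                "zone_len": zone_len,
                "H": H,
                "S": S,
                "F": F,
                "S_old": S_old,
                "F_old": F_old,
                "R": R,
                "k_deg": g.k_deg,
                "flux_as": F_as,
            }
        )

    enh_rows = []
    for e in genome.enhancers:
        H_e = _hazard(kin, z, s, 0.0, e.k_init)
        arm = kin.enhancer_arm
        S_e = float(np.exp(-H_e * arm))
        F_e = e.k_init * S_e
        if cond.assay == "cTT":
            level = F_e
        elif cond.assay == "cRNA":
            level = F_e * kin.unstable_lifetime_h
        elif cond.assay == "chip_polII":
            level = F_e / kin.elongation_rate
        else:
            level = 0.0
        mid = (e.start + e.end) // 2
        n_arm = arm // bw
        prof = np.full(n_arm, level)
        uid = e.id
        target_masses[uid] = 2 * level * arm
        nchrom = len(tracks["+"][e.chrom])
        lo_plus = mid // bw
        lo_minus = mid // bw - n_arm
        if lo_minus >= 0 and lo_plus + n_arm <= nchrom:
            paint("+", e.chrom, lo_plus, prof, True, uid)
            paint("-", e.chrom, lo_minus, prof, True, uid)
        else:
            written[uid] = 0.0
            target_masses[uid] = 0.0
        enh_rows.append({"id": e.id, "k_init": e.k_init, "F": F_e, "level": level})

    spike_masses = pd.Series(
        {sf.id: sf.abundance * sf.length for sf in genome.spike_features}
    )
    if cond.assay in CHIP_ASSAYS:
        input_target = pd.Series(
            {r["id"]: float(genome.genes[i].length)
             for i, r in enumerate(gene_rows)}
        )
        input_spike = pd.Series(
            {sf.id: float(sf.length) for sf in genome.spike_features}
        )
    else:
        input_target = None
        input_spike = None

    cov = {
        st: CoverageTrack(
            data=d, bin_width=bw, strand=st, sample_id=cond.label, calibrated=False
        )
        for st, d in tracks.items()
    }
    out = ExpectationSet(
        condition=cond,
        kinetics=kin,
        genes=pd.DataFrame(gene_rows).set_index("id"),
        enhancers=pd.DataFrame(enh_rows).set_index("id") if enh_rows else pd.DataFrame(),
        target_masses=pd.Series(target_masses),
        spike_masses=spike_masses,
        input_target_masses=input_target,
        input_spike_masses=input_spike,
        tracks=cov,
        unit_track_masses=pd.Series(written),
    )
    out.verify()
    return out


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Named substream of the master seed, stable under sample-set changes."""
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))]
        )
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * np.maximum(mu, 0.0))
    return rng.poisson(lam)


def sample_counts(
    expectations: ExpectationSet,
    condition: ConditionSpec | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> tuple[SampleCounts, SampleCounts | None]:
    """Draw a sequenced library (and matched input for ChIP assays).

    Per-feature counts are negative-binomial with mean
    ``depth * mass_i / total_mass`` where spike masses are scaled by the
    mixing ratio; dispersion is the kinetics ``phi``.  Deterministic for
    a fixed (seed, sample_id).
    """
    cond = condition or expectations.condition
    sid = sample_id or cond.label
    kin = expectations.kinetics
    m = cond.mixing_ratio

    tmass = expectations.target_masses
    smass = expectations.spike_masses * m
    total = tmass.sum() + smass.sum()
    rng = derive_rng(seed, sid)
    mu_t = cond.depth * tmass / total
    mu_s = cond.depth * smass / total
    sc = SampleCounts(
        sample_id=sid,
        target=pd.Series(_nb_draw(rng, mu_t.to_numpy(), kin.phi), index=tmass.index),
        spike=pd.Series(_nb_draw(rng, mu_s.to_numpy(), kin.phi), index=smass.index),
    )
    if expectations.input_target_masses is None:
        return sc, None

    itmass = expectations.input_target_masses
    ismass = expectations.input_spike_masses * m
    itotal = itmass.sum() + ismass.sum()
    irng = derive_rng(seed, sid + "_input")
    inp = SampleCounts(
        sample_id=sid + "_input",
        target=pd.Series(
            _nb_draw(irng, (cond.depth * itmass / itotal).to_numpy(), kin.phi),
            index=itmass.index,
        ),
        spike=pd.Series(
            _nb_draw(irng, (cond.depth * ismass / itotal).to_numpy(), kin.phi),
            index=ismass.index,
        ),
    )
    sc.input_sample_id = inp.sample_id
    return sc, inp


def sample_coverage(
    expectations: ExpectationSet,
    condition: ConditionSpec | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> dict[str, CoverageTrack]:
    """Draw per-bin read counts around the expected coverage tracks.

    Bin means are the expected coverage times the library's per-mass read
    yield (consistent with :func:`sample_counts`); bins are NB-distributed
    with the kinetics dispersion.
    """
    cond = condition or expectations.condition
    sid = sample_id or cond.label
    kin = expectations.kinetics
    total = (
        expectations.target_masses.sum()
        + (expectations.spike_masses * cond.mixing_ratio).sum()
    )
    scale = cond.depth / total * kin.bin_width
    out = {}
    for st, track in expectations.tracks.items():
        rng = derive_rng(seed, f"{sid}|cov{st}")
        data = {
            c: _nb_draw(rng, arr * scale, kin.phi).astype(float)
            for c, arr in track.data.items()
        }
        out[st] = CoverageTrack(
            data=data, bin_width=kin.bin_width, strand=st, sample_id=sid
        )
    return out
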