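"""Synthetic phased panels with known structure, drift, geography and
dated admixture pulses.

The generator is the truth-known stand-in for real cohort genotypes. Its
mechanisms are chosen to make downstream recovery analytically predictable:

* Allele-frequency drift per deme follows the Balding-Nichols model: deme
  frequencies are Beta-distributed around shared base frequencies with
  divergence parameter F in [0, 1].
* Recent, strong local drift (the kind producing extreme within-cluster
  coancestry) is modelled by drawing each haplotype as a Markov mosaic of a
  small pool of founder haplotypes, so deme members share long identical
  segments.
* A dated admixture pulse (proportion alpha, age g generations) rewrites each
  recipient haplotype as alternating ancestry tracts: tract boundaries follow
  a Poisson renewal process at rate g per Morgan and each segment's ancestry
  is an independent Bernoulli(alpha) draw from {source, local}. Adjacent
  same-ancestry segments are kept distinct in the truth record, so complete
  segment lengths are exactly Exponential with mean 100/g cM and the
  ancestry autocorrelation decays as exp(-g d) with d in Morgans -- the
  signal the dating module measures.

All randomness flows from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GeneticMap, HaplotypePanel

__all__ = [
    "DemeSpec",
    "DonorSpec",
    "PulseSpec",
    "GenomeSpec",
    "DemographicScenario",
    "TruthRecord",
    "simulate_structured_panel",
    "apply_admixture_pulse",
    "simulate_drift_admixture_scenario",
    "assign_geography",
]


@dataclass
class DemeSpec:
    """One sampled deme: label, diploid sample size, drift intensity F,
    planar centroid (km) and geographic dispersion (km).

    ``founders`` switches on the recent-drift founder-mosaic mechanism;
    ``pool`` names a shared ancestral frequency pool (default: private pool
    named after the deme).
    """

    label: str
    n: int
    drift: float = 0.0
    centroid: tuple = (0.0, 0.0)
    dispersion_km: float = 0.0
    founders: int | None = None
    founder_switch_per_cm: float = 0.1
    pool: str | None = None


@dataclass
class DonorSpec:
    """External donor population: label, diploid size, divergence from base."""

    label: str
    n: int
    divergence: float = 0.2
    founders: int | None = None
    founder_switch_per_cm: float = 0.1
    pool: str | None = None


@dataclass
class PulseSpec:
    """Single-generation admixture pulse from a source pool into a deme."""

    source: str
    recipient: str
    alpha: float
    g: int


@dataclass
class GenomeSpec:
    n_chrom: int = 2
    chrom_length_cm: float = 100.0
    snps_per_chrom: int = 200


@dataclass
class DemographicScenario:
    demes: list
    donors: list = field(default_factory=list)
    pulses: list = field(default_factory=list)
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    seed: int = 0

    def validate(self) -> None:
        labels = set()
        pools = set()
        for spec in list(self.demes) + list(self.donors):
            if spec.label in labels:
                raise ValueError(f"duplicate population label: {spec.label}")
            labels.add(spec.label)
            pools.add(spec.label)
            if spec.pool:
                pools.add(spec.pool)
            if spec.n < 2:
                raise ValueError(f"n must be >= 2 for {spec.label} (field n)")
            F = spec.drift if isinstance(spec, DemeSpec) else spec.divergence
            if not 0.0 <= F <= 1.0:
                raise ValueError(
                    f"drift/divergence must be in [0, 1] for {spec.label}"
                )
            if spec.founders is not None and spec.founders < 1:
                raise ValueError(f"founders must be >= 1 for {spec.label}")
        pools.add("base")
        deme_labels = {d.label for d in self.demes}
        for p in self.pulses:
            if not 0.0 <= p.alpha <= 1.0:
                raise ValueError(f"pulse alpha out of [0, 1]: {p.alpha} (field alpha)")
            if int(p.g) != p.g or p.g < 1:
                raise ValueError(f"pulse g must be an integer >= 1: {p.g} (field g)")
            if p.recipient not in deme_labels:
                raise ValueError(f"pulse recipient unknown: {p.recipient}")
            if p.source not in pools:
                raise ValueError(f"pulse source pool unknown: {p.source}")
        if self.genome.n_chrom < 1:
            raise ValueError("genome.n_chrom must be >= 1")
        if self.genome.chrom_length_cm <= 0:
            raise ValueError("genome.chrom_length_cm must be > 0")
        if self.genome.snps_per_chrom < 2:
            raise ValueError("genome.snps_per_chrom must be >= 2")


@dataclass
class TruthRecord:
    """Realized ground truth: per-haplotype ancestry tracts (renewal
    segments; adjacent same-source segments not merged), true deme label per
    individual, and the realized pulses."""

    tracts: pd.DataFrame  # hap, id, chrom, start_cm, end_cm, source
    deme_of: pd.Series  # id -> deme label
    pulses: list = field(default_factory=list)

    def tract_lengths(
        self, source: str | None = None, complete_only: bool = True
    ) -> np.ndarray:
        """Segment lengths in cM; ``complete_only`` drops chromosome-end
        censored segments so the remainder is exactly exponential."""
        t = self.tracts
        if complete_only:
            last = t.groupby(["hap", "chrom"])["end_cm"].transform("max")
            t = t[t["end_cm"] < last]
        if source is not None:
            t = t[t["source"] == source]
        return (t["end_cm"] - t["start_cm"]).to_numpy()

    def realized_alpha(self, deme: str, source: str) -> float:
        ids = self.deme_of[self.deme_of == deme].index
        t = self.tracts[self.tracts["id"].isin(ids)]
        total = (t["end_cm"] - t["start_cm"]).sum()
        src = t.loc[t["source"] == source, "end_cm"].sum() - t.loc[
            t["source"] == source, "start_cm"
        ].sum()
        return float(src / total) if total > 0 else 0.0

    def check_tiling(self, gmap: GeneticMap, atol: float = 1e-9) -> bool:
        spans = {c: gmap.span_cm(c) for c in gmap.chromosomes}
        start0 = {c: gmap.cm[gmap.chrom_slice(c)][0] for c in gmap.chromosomes}
        for (hap, chrom), seg in self.tracts.groupby(["hap", "chrom"]):
            seg = seg.sort_values("start_cm")
            if abs(seg["start_cm"].iloc[0] - start0[chrom]) > atol:
                return False
            if abs(seg["end_cm"].iloc[-1] - (start0[chrom] + spans[chrom])) > atol:
                return False
            if np.any(
                np.abs(seg["start_cm"].to_numpy()[1:] - seg["end_cm"].to_numpy()[:-1])
                > atol
            ):
                return False
        return True


class _Pool:
    """Ancestral pool: drifted allele frequencies plus optional founders."""

    def __init__(self, freqs, founders=None, founder_switch_per_cm=0.1):
        self.freqs = freqs
        self.founders = founders  # (K, S) or None
        self.founder_switch_per_cm = founder_switch_per_cm

    def draw_haplotypes(self, n_hap: int, gmap: GeneticMap, rng) -> np.ndarray:
        if self.founders is None:
            return (
                rng.random((n_hap, len(self.freqs))) < self.freqs[None, :]
            ).astype(np.int8)
        out = np.empty((n_hap, len(self.freqs)), dtype=np.int8)
        K = self.founders.shape[0]
        for c in gmap.chromosomes:
            sl = gmap.chrom_slice(c)
            cm = gmap.cm[sl]
            gaps = np.diff(cm)
            stay = np.exp(-self.founder_switch_per_cm * gaps)
            for h in range(n_hap):
                path = np.empty(len(cm), dtype=np.int64)
                path[0] = rng.integers(K)
                switch = rng.random(len(gaps)) >= stay
                for t in range(1, len(cm)):
                    path[t] = rng.integers(K) if switch[t - 1] else path[t - 1]
                out[h, sl] = self.founders[path, np.arange(sl.start, sl.stop) - sl.start]
        return out


def _drifted_freqs(base: np.ndarray, F: float, rng) -> np.ndarray:
    if F <= 0:
        return base.copy()
    if F >= 1:  # fully drifted: frequencies fixed at 0 or 1
        return (rng.random(len(base)) < base).astype(float)
    a = base * (1.0 - F) / F
    b = (1.0 - base) * (1.0 - F) / F
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def _build_map(genome: GenomeSpec) -> GeneticMap:
    chroms, bps, cms = [], [], []
    for c in range(1, genome.n_chrom + 1):
        cm = np.linspace(0.0, genome.chrom_length_cm, genome.snps_per_chrom)
        chroms.extend([f"chr{c}"] * len(cm))
        bps.extend((cm * 1e6).astype(np.int64) + 1)
        cms.extend(cm)
    return GeneticMap(np.array(chroms), np.array(bps), np.array(cms))


def _build_pools(scenario: DemographicScenario, gmap: GeneticMap, rng) -> dict:
    """One _Pool per population label (plus "base").

    Allele frequencies may be shared between populations via ``pool`` (the
    first population naming a frequency pool fixes its drift); founder
    haplotypes are always private to the population, so a deme can carry
    recent founder-mosaic drift on top of shared frequencies.
    """
    base = rng.uniform(0.05, 0.95, gmap.n_sites)
    freq_registry: dict[str, np.ndarray] = {"base": base}
    pools: dict[str, _Pool] = {"base": _Pool(base)}
    for spec in list(scenario.demes) + list(scenario.donors):
        fname = spec.pool or spec.label
        if fname not in freq_registry:
            F = spec.drift if isinstance(spec, DemeSpec) else spec.divergence
            freq_registry[fname] = _drifted_freqs(base, F, rng)
        freqs = freq_registry[fname]
        founders = None
        if spec.founders is not None:
            founders = (
                rng.random((spec.founders, gmap.n_sites)) < freqs[None, :]
            ).astype(np.int8)
        pools[spec.label] = _Pool(freqs, founders, spec.founder_switch_per_cm)
    return pools


def simulate_structured_panel(
    scenario: DemographicScenario,
) -> tuple[HaplotypePanel, TruthRecord]:
    """Draw a phased panel plus truth record for a demographic scenario.

    Deterministic under ``scenario.seed``; pulses listed in the scenario are
    applied in order via :func:`apply_admixture_pulse`.
    """
    scenario.validate()
    ss = np.random.SeedSequence(scenario.seed)
    children = ss.spawn(1 + len(scenario.pulses))
    rng = np.random.default_rng(children[0])
    gmap = _build_map(scenario.genome)
    pools = _build_pools(scenario, gmap, rng)

    hap_blocks, ids, rows = [], [], []
    for spec in list(scenario.demes) + list(scenario.donors):
        pool = pools[spec.label]  # private founders live on the label's pool
        haps = pool.draw_haplotypes(2 * spec.n, gmap, rng)
        hap_blocks.append(haps)
        role = "deme" if isinstance(spec, DemeSpec) else "donor"
        for i in range(spec.n):
            ids.append(f"{spec.label}_{i:03d}")
            rows.append({"group": spec.label, "role": role})
    meta = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    panel = HaplotypePanel(np.vstack(hap_blocks), ids, gmap, meta)

    # initial tracts: whole chromosomes from the population's own pool
    recs = []
    pool_of = {
        s.label: s.label for s in list(scenario.demes) + list(scenario.donors)
    }
    for h in range(panel.haplotypes.shape[0]):
        ind = panel.ids[h // 2]
        grp = meta.loc[ind, "group"]
        for c in gmap.chromosomes:
            cm = gmap.cm[gmap.chrom_slice(c)]
            recs.append(
                {
                    "hap": h,
                    "id": ind,
                    "chrom": c,
                    "start_cm": cm[0],
                    "end_cm": cm[-1],
                    "source": pool_of[grp],
                }
            )
    truth = TruthRecord(
        tracts=pd.DataFrame(recs),
        deme_of=meta["group"].copy(),
    )
    panel._pools = pools  # retained so pulses draw from the generating pools
    for k, p in enumerate(scenario.pulses):
        pulse_seed = int(children[1 + k].generate_state(1)[0] % (2**31))
        panel, truth = apply_admixture_pulse(
            panel, truth, p.source, p.recipient, p.alpha, p.g, pulse_seed
        )
    return panel, truth


def apply_admixture_pulse(
    panel: HaplotypePanel,
    truth: TruthRecord,
    source: str,
    recipient: str,
    alpha: float,
    g: int,
    seed: int,
) -> tuple[HaplotypePanel, TruthRecord]:
    """Rewrite each recipient-deme haplotype as alternating ancestry tracts.

    Tract boundaries follow a Poisson renewal process with rate g per Morgan
    and each segment independently carries source ancestry with probability
    alpha; source segments receive allele content drawn fresh from the source
    pool's generating distribution.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha out of [0, 1]: {alpha}")
    if g < 1:
        raise ValueError(f"g must be >= 1: {g}")
    pools = getattr(panel, "_pools", None)
    if pools is None or source not in pools:
        raise ValueError(f"unknown source pool: {source}")
    members = truth.deme_of[truth.deme_of == recipient].index
    if len(members) == 0:
        raise ValueError(f"unknown recipient deme: {recipient}")
    if alpha == 0.0:
        return panel, truth

    rng = np.random.default_rng(seed)
    gmap = panel.gmap
    haps = panel.haplotypes.copy()
    idx_of = {v: k for k, v in enumerate(panel.ids)}
    hap_rows = []
    for ind in members:
        hap_rows.extend([2 * idx_of[ind], 2 * idx_of[ind] + 1])

    old = truth.tracts
    keep = old[~old["hap"].isin(hap_rows)]
    new_recs = []
    rate = g / 100.0  # per cM
    for h in hap_rows:
        ind = panel.ids[h // 2]
        src_hap = pools[source].draw_haplotypes(1, gmap, rng)[0]
        for c in gmap.chromosomes:
            sl = gmap.chrom_slice(c)
            cm = gmap.cm[sl]
            lo, hi = cm[0], cm[-1]
            # renewal boundaries at rate g per Morgan
            bounds = [lo]
            x = lo
            while True:
                x = x + rng.exponential(1.0 / rate)
                if x >= hi:
                    break
                bounds.append(x)
            bounds.append(hi)
            prior = old[(old["hap"] == h) & (old["chrom"] == c)].sort_values(
                "start_cm"
            )
            for s0, s1 in zip(bounds[:-1], bounds[1:]):
                is_src = rng.random() < alpha
                if is_src:
                    in_seg = (cm >= s0) & (cm < s1)
                    if s1 == hi:
                        in_seg = (cm >= s0) & (cm <= s1)
                    cols = np.flatnonzero(in_seg) + sl.start
                    haps[h, cols] = src_hap[cols]
                    new_recs.append(
                        {
                            "hap": h,
                            "id": ind,
                            "chrom": c,
                            "start_cm": s0,
                            "end_cm": s1,
                            "source": source,
                        }
                    )
                else:
                    # retain prior ancestry labels across this segment
                    for _, r in prior.iterrows():
                        a = max(s0, r["start_cm"])
                        b = min(s1, r["end_cm"])
                        if b > a or (b == a == hi and s0 < s1):
                            new_recs.append(
                                {
                                    "hap": h,
                                    "id": ind,
                                    "chrom": c,
                                    "start_cm": a,
                                    "end_cm": max(b, a),
                                    "source": r["source"],
                                }
                            )
    tracts = pd.concat([keep, pd.DataFrame(new_recs)], ignore_index=True)
    tracts = tracts.sort_values(["hap", "chrom", "start_cm"]).reset_index(drop=True)
    new_panel = HaplotypePanel(haps, panel.ids, gmap, panel.metadata.copy())
    new_panel._pools = pools
    new_truth = TruthRecord(
        tracts=tracts,
        deme_of=truth.deme_of.copy(),
        pulses=truth.pulses + [(source, recipient, alpha, g)],
    )
    return new_panel, new_truth


def simulate_drift_admixture_scenario(
    which: str,
    seed: int,
    n_per_deme: int = 16,
    genome: GenomeSpec | None = None,
) -> tuple[HaplotypePanel, TruthRecord]:
    """Two-population drift/admixture cartoons for the coancestry test.

    The panel always contains the clusters of interest ``alpha`` and ``beta``
    plus two unadmixed background demes sharing beta's ancestral pool. The
    backgrounds keep beta's within-cluster background copying diffuse, which
    is what lets admixture from a highly drifted alpha' produce higher
    cross-coancestry of beta with alpha than within beta -- with only two
    clusters and equal subsample sizes that ordering is unobtainable because
    beta's background copying concentrates on its own few co-members.

    ``which`` is one of "split", "mix-into-alpha",
    "mix-into-beta-from-drifted", "bidirectional".
    """
    if genome is None:
        genome = GenomeSpec(n_chrom=2, chrom_length_cm=100.0, snps_per_chrom=150)
    known = {"split", "mix-into-alpha", "mix-into-beta-from-drifted", "bidirectional"}
    if which not in known:
        raise ValueError(f"unknown scenario: {which!r} (choose from {sorted(known)})")

    drifted = which in ("mix-into-beta-from-drifted", "bidirectional")
    alpha_drift = 0.4 if drifted else 0.1
    demes = [
        DemeSpec("alpha", n_per_deme, drift=alpha_drift, centroid=(0.0, 0.0)),
        DemeSpec("beta", n_per_deme, drift=0.02, centroid=(200.0, 0.0)),
        DemeSpec("bg1", n_per_deme, drift=0.02, centroid=(400.0, 0.0)),
        DemeSpec("bg2", n_per_deme, drift=0.02, centroid=(600.0, 0.0)),
    ]
    pulses = []
    if which == "mix-into-alpha":
        pulses = [PulseSpec(source="beta", recipient="alpha", alpha=0.3, g=20)]
    elif which == "mix-into-beta-from-drifted":
        pulses = [PulseSpec(source="alpha", recipient="beta", alpha=0.45, g=20)]
    elif which == "bidirectional":
        pulses = [
            PulseSpec(source="alpha", recipient="beta", alpha=0.45, g=20),
            PulseSpec(source="beta", recipient="alpha", alpha=0.2, g=20),
        ]
    scenario = DemographicScenario(demes=demes, pulses=pulses, genome=genome, seed=seed)
    return simulate_structured_panel(scenario)


def assign_geography(
    panel: HaplotypePanel,
    scenario: DemographicScenario,
    seed: int | None = None,
    distant_fraction: float = 0.0,
    distant_km: float = 150.0,
) -> pd.DataFrame:
    """Draw four grandparental birthplace coordinates per deme individual.

    Coordinates are isotropic Gaussian around the deme centroid with the
    deme's dispersion as per-axis standard deviation; a configurable fraction
    of individuals get one grandparent displaced by ``distant_km`` (to
    exercise the 80-km retention filter). Returns the augmented metadata,
    which is also stored back on the panel.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    meta = panel.metadata.copy()
    for col in ["x_km", "y_km"] + [f"gp{k}_{ax}" for k in range(1, 5) for ax in "xy"]:
        meta[col] = np.nan
    centroids = {d.label: d for d in scenario.demes}
    for ind in meta.index:
        grp = meta.loc[ind, "group"]
        if grp not in centroids:
            continue
        spec = centroids[grp]
        cx, cy = spec.centroid
        gp = rng.normal(
            loc=[cx, cy], scale=max(spec.dispersion_km, 0.0), size=(4, 2)
        ) if spec.dispersion_km > 0 else np.tile([cx, cy], (4, 1)).astype(float)
        if distant_fraction > 0 and rng.random() < distant_fraction:
            angle = rng.uniform(0, 2 * np.pi)
            gp[3] += distant_km * np.array([np.cos(angle), np.sin(angle)])
        for k in range(4):
            meta.loc[ind, f"gp{k + 1}_x"] = gp[k, 0]
            meta.loc[ind, f"gp{k + 1}_y"] = gp[k, 1]
        meta.loc[ind, "x_km"] = gp[:, 0].mean()
        meta.loc[ind, "y_km"] = gp[:, 1].mean()
    panel.metadata = meta
    return meta
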