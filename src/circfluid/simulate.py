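"""Ground-truthed synthetic inputs for the full harmonization pipeline.

The generator emulates a longitudinal two-biofluid circRNA study: a
synthetic transcript annotation; a truth set of back-splice junctions
planted at known genomic features; participants sampled repeatedly with
participant-specific multiplicative expression profiles; per-sample
back-spliced counts drawn from a negative binomial around
``abundance x participant offset x library size``; and, per sample, one
native-format output file for each of the six callers (with the caller's
own coordinate basis, independent per-tool dropout and false positives), a
STAR SJ.out.tab holding the planted linear flanks plus decoys, and the
sample-metadata/junction-totals table.

Everything emitted is derivable from the :class:`TruthManifest`, so every
pipeline stage can be checked against closed-form expectations.

Truth junctions are guaranteed to pass the per-tool detection filters
before tool noise is applied (counts are raised to ``min_reads`` in the
top expected-abundance samples where sampling left fewer than
``min_samples`` qualifying samples).  This makes noiseless recovery exact
by construction, so recovery tests measure pipeline correctness rather
than sampling luck; dropout and false positives then perturb the per-tool
views independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import SampleMeta, TranscriptModel
from .junctions import TOOLS, BackspliceJunction

__all__ = ["GeneratorConfig", "TruthJunction", "TruthManifest",
           "simulate_truth", "emit_files"]

BIOFLUIDS = ("plasma", "urine")


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters for the generator.

    Defaults describe a small longitudinal cohort: 12 participants each
    contributing plasma and urine, 4 of them sampled 6 times (the
    longitudinal arm) and the rest twice; 300 truth junctions per biofluid
    with 85% of the urine set shared with plasma; log-normal baseline
    abundances on the JRPM scale; log-normal participant offsets; negative
    binomial counts; per-sample library sizes (total junction reads) of
    2-8 x 10^5.  Per-tool dropout rates mirror the observed ordering of
    caller sensitivities (one permissive, one conservative caller).
    """

    n_participants: int = 12
    n_long_participants: int = 4
    long_visits: int = 6
    short_visits: int = 2
    n_truth_junctions: int = 300
    shared_fraction: float = 0.85
    # ln-scale parameters of the baseline JRPM distribution
    abundance_log_mean: float = 1.6
    abundance_log_sd: float = 1.2
    participant_effect_sd: float = 0.5
    nb_dispersion: float = 5.0
    library_size_range: tuple[int, int] = (200_000, 800_000)
    # linear-flank model
    flank_fraction: float = 0.8
    flank_mean_reads: float = 20.0
    split_flank_fraction: float = 0.2
    n_decoy_linear: int = 60
    decoy_linear_mean: float = 10.0
    # per-tool noise
    dropout: dict[str, float] = field(default_factory=lambda: {
        "circexplorer": 0.06, "ciri2": 0.05, "dcc": 0.05,
        "find_circ": 0.12, "knife": 0.02, "mapsplice": 0.15,
    })
    fp_rate: dict[str, float] = field(default_factory=lambda: {t: 0.02 for t in TOOLS})
    n_fp_loci: int = 150
    # planted feature-class mix (multi-exon, single-exon, intronic, intergenic)
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "multi_exon_spanning_intron": 0.70,
        "single_exon": 0.02,
        "intronic": 0.08,
        "intergenic": 0.20,
    })
    # synthetic genome
    n_chroms: int = 4
    transcripts_per_chrom: int = 60
    # detectability guarantee thresholds (match the detection filters)
    guarantee_min_reads: int = 2
    guarantee_min_samples: int = 5

    def __post_init__(self) -> None:
        for name, p in [("shared_fraction", self.shared_fraction),
                        ("flank_fraction", self.flank_fraction),
                        ("split_flank_fraction", self.split_flank_fraction),
                        *[(f"dropout[{t}]", v) for t, v in self.dropout.items()],
                        *[(f"fp_rate[{t}]", v) for t, v in self.fp_rate.items()]]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.n_truth_junctions <= 0 or self.n_participants <= 0:
            raise ValueError("sizes must be positive")
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.n_long_participants > self.n_participants:
            raise ValueError("more longitudinal participants than participants")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthJunction:
    junction: BackspliceJunction
    biofluids: tuple[str, ...]
    base_abundance: float          # expected JRPM
    host_transcript: str | None
    planted_class: str
    has_flanks: bool
    split_flank: bool

    @property
    def key(self) -> str:
        return self.junction.unstranded_key


@dataclass
class TruthManifest:
    """Complete ground truth for one simulated study."""

    seed: int
    config: GeneratorConfig
    transcripts: list[TranscriptModel]
    junctions: list[TruthJunction]
    samples: list[SampleMeta]
    offsets: pd.DataFrame                       # junction_key x participant
    true_counts: dict[str, pd.DataFrame]        # biofluid -> key x sample
    tool_counts: dict[str, dict[str, pd.DataFrame]]
    linear5: dict[str, pd.DataFrame]            # biofluid -> key x sample
    linear3: dict[str, pd.DataFrame]
    fp_keys: list[str]
    decoy_linear: pd.DataFrame                  # loci x sample counts
    decoy_linear_loci: list[tuple[str, int, int]]

    def truth_keys(self, biofluid: str) -> set[str]:
        return {tj.key for tj in self.junctions if biofluid in tj.biofluids}

    def samples_of(self, biofluid: str) -> list[SampleMeta]:
        return [s for s in self.samples if s.biofluid == biofluid]

    def junction_by_key(self) -> dict[str, TruthJunction]:
        return {tj.key: tj for tj in self.junctions}


# ---------------------------------------------------------------------------
# genome / truth placement

def _make_transcripts(cfg: GeneratorConfig, rng: np.random.Generator
                      ) -> list[TranscriptModel]:
    transcripts = []
    gi = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 10_000
        for _ in range(cfg.transcripts_per_chrom):
            gi += 1
            n_ex = int(rng.integers(4, 9))
            sizes = rng.integers(120, 301, size=n_ex)
            introns = rng.integers(300, 1501, size=n_ex - 1)
            starts = [0]
            for k in range(1, n_ex):
                starts.append(starts[-1] + int(sizes[k - 1]) + int(introns[k - 1]))
            tx_start = pos
            tx_end = tx_start + starts[-1] + int(sizes[-1])
            strand = "+" if rng.random() < 0.5 else "-"
            # CDS: inside exon 1 through inside the last exon, leaving UTRs
            cds_start = tx_start + int(sizes[0]) // 2
            cds_end = tx_end - int(sizes[-1]) // 2
            transcripts.append(TranscriptModel(
                chrom=chrom, tx_start0=tx_start, tx_end0=tx_end,
                name=f"GENE{gi:04d}", strand=strand,
                cds_start0=cds_start, cds_end0=cds_end,
                block_sizes=tuple(int(s) for s in sizes),
                block_starts=tuple(starts),
            ))
            pos = tx_end + int(rng.integers(8_000, 15_000))
    return transcripts


def _place_junctions(cfg: GeneratorConfig, rng: np.random.Generator,
                     transcripts: list[TranscriptModel], n_total: int
                     ) -> list[tuple[BackspliceJunction, str | None, str]]:
    """Place ``n_total`` junctions at known features, with unique acceptor
    and donor coordinates (so flank splice sites never collide)."""
    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])
    used_acceptors: set[tuple[str, int]] = set()
    used_donors: set[tuple[str, int]] = set()
    chrom_ends = {}
    for tx in transcripts:
        chrom_ends[tx.chrom] = max(chrom_ends.get(tx.chrom, 0), tx.tx_end0)

    placed = []
    attempts = 0
    while len(placed) < n_total:
        attempts += 1
        if attempts > 200 * n_total:
            raise ValueError("cannot place truth junctions: config infeasible")
        cls = classes[int(rng.choice(len(classes), p=probs))]
        if cls == "intergenic":
            chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
            start = int(rng.integers(chrom_ends[chrom] + 20_000,
                                     chrom_ends[chrom] + 2_000_000))
            end = start + int(rng.integers(200, 2_000))
            j = BackspliceJunction(chrom, start, end, "+")
            host = None
        else:
            tx = transcripts[int(rng.integers(len(transcripts)))]
            exons = tx.exons
            if cls == "multi_exon_spanning_intron":
                if len(exons) < 4:
                    continue
                i = int(rng.integers(1, len(exons) - 2))
                jj = int(rng.integers(i + 1, len(exons) - 1))
                j = BackspliceJunction(tx.chrom, exons[i][0], exons[jj][1],
                                       tx.strand)
            elif cls == "single_exon":
                s, e = exons[int(rng.integers(len(exons)))]
                if e - s < 80:
                    continue
                j = BackspliceJunction(tx.chrom, s + 10, e - 10, tx.strand)
            else:  # intronic
                intr = tx.introns
                s, e = intr[int(rng.integers(len(intr)))]
                if e - s < 120:
                    continue
                j = BackspliceJunction(tx.chrom, s + 20, e - 20, tx.strand)
            host = tx.name
        ka, kd = (j.chrom, j.start0), (j.chrom, j.end0)
        if ka in used_acceptors or kd in used_donors:
            continue
        used_acceptors.add(ka)
        used_donors.add(kd)
        placed.append((j, host, cls))
    return placed


def _place_fp_loci(cfg: GeneratorConfig, rng: np.random.Generator,
                   taken: set[str]) -> list[BackspliceJunction]:
    loci = []
    while len(loci) < cfg.n_fp_loci:
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        start = int(rng.integers(5_000_000, 9_000_000))
        end = start + int(rng.integers(150, 3_000))
        j = BackspliceJunction(chrom, start, end, "+")
        if j.unstranded_key in taken:
            continue
        taken.add(j.unstranded_key)
        loci.append(j)
    return loci


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """Negative binomial with the given mean and size (dispersion) parameter."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_truth(config: GeneratorConfig | None = None, seed: int = 0
                   ) -> TruthManifest:
    """Draw a complete ground-truthed study; deterministic in (config, seed)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    transcripts = _make_transcripts(cfg, rng)

    # truth pool: plasma set, plus urine extras beyond the shared part
    n_shared = int(round(cfg.shared_fraction * cfg.n_truth_junctions))
    n_pool = 2 * cfg.n_truth_junctions - n_shared
    placed = _place_junctions(cfg, rng, transcripts, n_pool)
    plasma_slice = placed[:cfg.n_truth_junctions]
    shared_slice = placed[:n_shared]
    urine_extra = placed[cfg.n_truth_junctions:]
    fluid_of: dict[str, set[str]] = {}
    for j, _, _ in plasma_slice:
        fluid_of.setdefault(j.unstranded_key, set()).add("plasma")
    for j, _, _ in shared_slice + urine_extra:
        fluid_of.setdefault(j.unstranded_key, set()).add("urine")

    abundances = np.exp(rng.normal(cfg.abundance_log_mean, cfg.abundance_log_sd,
                                   size=len(placed)))
    has_flanks = rng.random(len(placed)) < cfg.flank_fraction
    split_flank = (rng.random(len(placed)) < cfg.split_flank_fraction) & has_flanks

    junctions = [
        TruthJunction(
            junction=j,
            biofluids=tuple(sorted(fluid_of[j.unstranded_key])),
            base_abundance=float(abundances[i]),
            host_transcript=host,
            planted_class=cls,
            has_flanks=bool(has_flanks[i]),
            split_flank=bool(split_flank[i]),
        )
        for i, (j, host, cls) in enumerate(placed)
    ]
    all_keys = [tj.key for tj in junctions]

    # participants, visits, samples
    participants = [f"P{i + 1:02d}" for i in range(cfg.n_participants)]
    visits = {
        pid: (cfg.long_visits if i < cfg.n_long_participants else cfg.short_visits)
        for i, pid in enumerate(participants)
    }
    offsets = pd.DataFrame(
        np.exp(rng.normal(0.0, cfg.participant_effect_sd,
                          size=(len(all_keys), len(participants)))),
        index=all_keys, columns=participants,
    )

    lo, hi = cfg.library_size_range
    sample_rows = []  # (sample_id, pid, fluid, visit, library_size)
    for fluid in BIOFLUIDS:
        for pid in participants:
            for v in range(1, visits[pid] + 1):
                sid = f"{pid}_{fluid}_v{v}"
                sample_rows.append((sid, pid, fluid, v, int(rng.integers(lo, hi + 1))))

    true_counts: dict[str, pd.DataFrame] = {}
    linear5: dict[str, pd.DataFrame] = {}
    linear3: dict[str, pd.DataFrame] = {}
    tool_counts: dict[str, dict[str, pd.DataFrame]] = {}
    samples: list[SampleMeta] = []

    fp_loci = _place_fp_loci(cfg, rng, set(all_keys))
    fp_keys = [j.unstranded_key for j in fp_loci]

    for fluid in BIOFLUIDS:
        rows = [r for r in sample_rows if r[2] == fluid]
        sids = [r[0] for r in rows]
        keys = sorted(k for k in all_keys if fluid in fluid_of[k])
        ab = pd.Series({tj.key: tj.base_abundance for tj in junctions})[keys]
        lib = np.array([r[4] for r in rows], dtype=float)
        off = offsets.loc[keys, [r[1] for r in rows]].to_numpy()
        mu = ab.to_numpy()[:, None] * off * lib[None, :] / 1e6
        counts = _nb_draw(rng, mu, cfg.nb_dispersion).astype(int)

        # detectability guarantee: every truth junction has >= min_reads in
        # >= min_samples samples before tool noise
        need, thr = cfg.guarantee_min_samples, cfg.guarantee_min_reads
        for r in range(counts.shape[0]):
            ok = counts[r] >= thr
            deficit = need - int(ok.sum())
            if deficit > 0:
                candidates = np.argsort(-mu[r])
                for c in candidates:
                    if counts[r, c] < thr:
                        counts[r, c] = thr
                        deficit -= 1
                        if deficit == 0:
                            break
        cdf = pd.DataFrame(counts, index=keys, columns=sids)
        true_counts[fluid] = cdf

        # sample totals: chimeric = back-spliced reads emitted, canonical fills
        # the library size
        for (sid, pid, _, v, L) in rows:
            chim = int(cdf[sid].sum())
            samples.append(SampleMeta(
                sample_id=sid, participant_id=pid, biofluid=fluid,
                visit_index=v, canonical_junction_reads=L - chim,
                chimeric_junction_reads=chim,
            ))

        # linear flanks
        tj_by_key = {tj.key: tj for tj in junctions}
        fl_mask = np.array([tj_by_key[k].has_flanks for k in keys])
        l5 = _nb_draw(rng, np.full((len(keys), len(sids)), cfg.flank_mean_reads),
                      cfg.nb_dispersion)
        l3 = _nb_draw(rng, np.full((len(keys), len(sids)), cfg.flank_mean_reads),
                      cfg.nb_dispersion)
        l5[~fl_mask] = 0
        l3[~fl_mask] = 0
        linear5[fluid] = pd.DataFrame(l5.astype(int), index=keys, columns=sids)
        linear3[fluid] = pd.DataFrame(l3.astype(int), index=keys, columns=sids)

        # per-tool observed counts: independent dropout + false positives
        tool_counts[fluid] = {}
        for tool in TOOLS:
            drop = rng.random(cdf.shape) < cfg.dropout[tool]
            obs = cdf.to_numpy().copy()
            obs[drop] = 0
            fp_present = rng.random((len(fp_keys), len(sids))) < cfg.fp_rate[tool]
            fp_counts = (cfg.guarantee_min_reads
                         + rng.poisson(1.0, size=fp_present.shape)) * fp_present
            full = pd.DataFrame(
                np.vstack([obs, fp_counts]).astype(int),
                index=keys + fp_keys, columns=sids,
            )
            tool_counts[fluid][tool] = full

    # decoy linear junctions (shared loci, per-sample Poisson counts)
    decoy_loci = []
    flank_sites = set()
    for tj in junctions:
        flank_sites.add((tj.junction.chrom, tj.junction.start0))
        flank_sites.add((tj.junction.chrom, tj.junction.end0 + 1))
    while len(decoy_loci) < cfg.n_decoy_linear:
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        s = int(rng.integers(1, 4_000_000))
        e = s + int(rng.integers(80, 5_000))
        if (chrom, e) in flank_sites or (chrom, s) in flank_sites:
            continue
        decoy_loci.append((chrom, s, e))
    all_sids = [r[0] for r in sample_rows]
    decoy = pd.DataFrame(
        rng.poisson(cfg.decoy_linear_mean, size=(len(decoy_loci), len(all_sids))),
        index=range(len(decoy_loci)), columns=all_sids,
    )

    return TruthManifest(
        seed=seed, config=cfg, transcripts=transcripts, junctions=junctions,
        samples=samples, offsets=offsets, true_counts=true_counts,
        tool_counts=tool_counts, linear5=linear5, linear3=linear3,
        fp_keys=fp_keys, decoy_linear=decoy, decoy_linear_loci=decoy_loci,
    )


# ---------------------------------------------------------------------------
# dialect writers (mirror the io readers)

def _write_circexplorer(path: Path, rows: Iterable[tuple[BackspliceJunction, int]]):
    with path.open("w") as fh:
        for j, n in rows:
            size = j.end0 - j.start0
            fh.write("\t".join((
                j.chrom, str(j.start0), str(j.end0), "circular_RNA/1", "0",
                j.strand, str(j.start0), str(j.end0), "0,0,0", "1",
                f"{size},", "0,", str(n),
            )) + "\n")


def _write_ciri2(path: Path, rows):
    with path.open("w") as fh:
        fh.write("circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\t"
                 "SM_MS_SMS\t#non_junction_reads\tjunction_reads_ratio\t"
                 "circRNA_type\tgene_id\tstrand\n")
        for j, n in rows:
            cid = f"{j.chrom}:{j.start0 + 1}|{j.end0}"
            fh.write("\t".join((
                cid, j.chrom, str(j.start0 + 1), str(j.end0), str(n),
                f"{n}_0_0", "0", "1.0", "exon", "n/a", j.strand,
            )) + "\n")


def _write_dcc(path: Path, rows, sample_id: str):
    with path.open("w") as fh:
        fh.write(f"Chr\tStart\tEnd\tStrand\t{sample_id}\n")
        for j, n in rows:
            fh.write("\t".join((
                j.chrom, str(j.start0 + 1), str(j.end0), j.strand, str(n),
            )) + "\n")


def _write_find_circ(path: Path, rows):
    with path.open("w") as fh:
        for i, (j, n) in enumerate(rows):
            fh.write("\t".join((
                j.chrom, str(j.start0), str(j.end0), f"norm_{i}", str(n),
                j.strand,
            )) + "\n")


def _write_knife(path: Path, rows):
    with path.open("w") as fh:
        fh.write("junction\treadCount\n")
        for j, n in rows:
            token = (f"{j.chrom}|GENEA:{j.start0}|GENEB:{j.end0}|rev|"
                     f"{j.strand if j.strand != '.' else '+'}")
            fh.write(f"{token}\t{n}\n")


def _write_mapsplice(path: Path, rows):
    # donor-first 1-based coordinate pair, as MapSplice reports back-splices
    with path.open("w") as fh:
        for i, (j, n) in enumerate(rows):
            s = j.strand if j.strand != "." else "+"
            fh.write("\t".join((
                f"{j.chrom}~{j.chrom}", str(j.end0), str(j.start0 + 1),
                f"CIRC_{i}", str(n), s + s,
            )) + "\n")


_TOOL_WRITERS = {
    "circexplorer": lambda p, r, sid: _write_circexplorer(p, r),
    "ciri2": lambda p, r, sid: _write_ciri2(p, r),
    "dcc": _write_dcc,
    "find_circ": lambda p, r, sid: _write_find_circ(p, r),
    "knife": lambda p, r, sid: _write_knife(p, r),
    "mapsplice": lambda p, r, sid: _write_mapsplice(p, r),
}


def emit_files(manifest: TruthManifest, out_dir: str | Path) -> Path:
    """Serialize a manifest into the on-disk study layout.

    Layout::

        out_dir/
          annotation.bed          BED12 transcript models
          samples.tsv             sample metadata + junction totals
          truth.json              truth keys, classes, abundances (for audit)
          tools/<tool>/<sample_id>.tsv   caller-native output per sample
          sj/<sample_id>.SJ.out.tab      linear splice junctions per sample
    """
    out = Path(out_dir)
    (out / "sj").mkdir(parents=True, exist_ok=True)
    for tool in TOOLS:
        (out / "tools" / tool).mkdir(parents=True, exist_ok=True)

    with (out / "annotation.bed").open("w") as fh:
        for tx in manifest.transcripts:
            fh.write(tx.to_bed12() + "\n")

    meta = pd.DataFrame(
        [(s.sample_id, s.participant_id, s.biofluid, s.visit_index,
          s.canonical_junction_reads, s.chimeric_junction_reads)
         for s in manifest.samples],
        columns=["sample_id", "participant_id", "biofluid", "visit_index",
                 "canonical_junction_reads", "chimeric_junction_reads"],
    )
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)

    jobj = {j.unstranded_key: j for j in
            [tj.junction for tj in manifest.junctions]}
    for j in (BackspliceJunction.from_key(k) for k in manifest.fp_keys):
        jobj[j.unstranded_key] = j
    by_key = manifest.junction_by_key()

    for fluid in BIOFLUIDS:
        sids = [s.sample_id for s in manifest.samples_of(fluid)]
        for tool in TOOLS:
            counts = manifest.tool_counts[fluid][tool]
            for sid in sids:
                col = counts[sid]
                rows = [(jobj[k], int(col[k])) for k in counts.index if col[k] > 0]
                _TOOL_WRITERS[tool](out / "tools" / tool / f"{sid}.tsv", rows, sid)

        # splice-site coordinate sets; the far end of each emitted flank
        # intron must avoid them so no SJ row matches a foreign junction
        acceptor_sites = {(j.chrom, j.start0) for j in jobj.values()}
        donor_sites = {(j.chrom, j.end0 + 1) for j in jobj.values()}

        def _five_prime_row(j: BackspliceJunction, length: int, c: int):
            s = j.start0 - length
            while (j.chrom, s) in donor_sites:  # would also match a 3' flank
                s -= 1
            return (j.chrom, s, j.start0, c)

        def _three_prime_row(j: BackspliceJunction, length: int, c: int):
            e = j.end0 + length
            while (j.chrom, e) in acceptor_sites:  # would also match a 5' flank
                e += 1
            return (j.chrom, j.end0 + 1, e, c)

        l5, l3 = manifest.linear5[fluid], manifest.linear3[fluid]
        for sid in sids:
            lines = []
            for k in l5.index:
                j = jobj[k]
                tj = by_key[k]
                c5, c3 = int(l5.at[k, sid]), int(l3.at[k, sid])
                if c5 > 0:
                    # intron ends at the base before the circle: intron_end1 == start0
                    if tj.split_flank and c5 > 1:
                        a, b = c5 // 2, c5 - c5 // 2
                        lines.append(_five_prime_row(j, 800, a))
                        lines.append(_five_prime_row(j, 400, b))
                    else:
                        lines.append(_five_prime_row(j, 400, c5))
                if c3 > 0:
                    lines.append(_three_prime_row(j, 400, c3))
            for li, (chrom, s, e) in enumerate(manifest.decoy_linear_loci):
                c = int(manifest.decoy_linear.at[li, sid])
                if c > 0:
                    lines.append((chrom, s, e, c))
            lines.sort()
            with (out / "sj" / f"{sid}.SJ.out.tab").open("w") as fh:
                for chrom, s, e, c in lines:
                    fh.write(f"{chrom}\t{s}\t{e}\t1\t1\t1\t{c}\t0\t30\n")

    truth = {
        "seed": manifest.seed,
        "truth_junctions": [
            {"key": tj.key, "biofluids": list(tj.biofluids),
             "base_abundance": tj.base_abundance,
             "host_transcript": tj.host_transcript,
             "planted_class": tj.planted_class,
             "has_flanks": tj.has_flanks}
            for tj in manifest.junctions
        ],
        "fp_keys": manifest.fp_keys,
    }
    with (out / "truth.json").open("w") as fh:
        json.dump(truth, fh, indent=1)
    return out
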