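"""Synthetic genomes, context tracks, and interaction maps with planted
structure.

The generator emulates the statistical structure of an RNA-chromatin
interaction study so that every downstream stage is testable without
external data:

* interaction probability decays exponentially with distance from the
  lncRNA gene (the cis concentration of real maps);
* each lncRNA binds through one planted mechanism — a *transcription*-like
  autocorrelated context track, a *triplex*-like lncRNA x tile sequence
  feature (purine-tract inserts matching a triplex element carried by the
  lncRNA), an *XOR pair* of context tracks informative only jointly, or
  pure *noise* (distance only);
* context tracks are piecewise constant with geometric block lengths, so
  they are spatially autocorrelated;
* a shared 5-mer enrichment (``kmer_bias``) shapes lncRNA transcripts,
  miRNA seeds, repeat consensus sequences and the planted triplex element,
  so k-mer density correlations exist by construction.

Binding probability composes distance and signal multiplicatively:
p(tile) prop-to exp(-d / decay_scale) * sigmoid(effect_size * s(tile)) with
s in {-1, +1}, so distance-matched negatives remain informative about the
planted signal only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import TiledGenome, tile_genome
from .interactome import InteractionMap, LncRNA
from .kmers import canonical_kmers

__all__ = ["LncSpec", "SyntheticConfig", "purine_graded_bias", "lognormal_bias", "SyntheticGenome",
           "SyntheticTracks", "generate_genome", "generate_context_tracks",
           "generate_interactions", "xor_indicator"]

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

MECHANISMS = ("transcription", "triplex", "xor_pair", "noise")


def purine_graded_bias(gamma: float = 2.0, k: int = 5) -> dict[str, float]:
    """k-mer bias graded by purine content: weight gamma**(#purines).

    Ties the sequence sharing to the triplex story: the highest-weight
    5-mers are the all-A/G ones that make up triplex target tracts.
    """
    out = {}
    for km in canonical_kmers(k):
        out[km] = gamma ** sum(1 for b in km if b in "AG")
    return out


def lognormal_bias(seed: int, sigma: float = 1.5, k: int = 5) -> dict[str, float]:
    """Heavy-tailed random k-mer bias: i.i.d. LogNormal(0, sigma) weights.

    Gives a continuous enrichment gradient across many 5-mers (a few strong,
    many moderate), which is what makes density/importance rank correlations
    informative rather than driven by a handful of k-mers.
    """
    rng = np.random.default_rng(seed)
    kmers = canonical_kmers(k)
    w = np.exp(sigma * rng.normal(size=len(kmers)))
    return dict(zip(kmers, w.tolist()))


@dataclass(frozen=True)
class LncSpec:
    """One planted lncRNA: gene placement, mechanism, and effect size."""

    name: str
    chrom: str
    gene_start: int
    gene_end: int
    mechanism: str
    effect_size: float = 2.0
    n_target_positives: int = 1000
    #: optional per-lncRNA k-mer bias (transcript + triplex element); the
    #: config-wide bias applies when None
    kmer_bias: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.gene_end <= self.gene_start:
            raise ValueError("empty gene interval")


@dataclass(frozen=True)
class SyntheticConfig:
    n_chroms: int
    chrom_length: int
    lncrnas: tuple[LncSpec, ...]
    tile_width: int = 1000
    decay_scale: float = 250_000.0
    seed: int = 0
    kmer_bias: dict[str, float] = field(default_factory=dict)
    track_block_length: float = 10_000.0
    # generator internals
    transcript_length: int = 6000
    biased_fraction: float = 0.9        # fraction of biased-chain sequence in transcripts
    insert_rate: float = 0.25           # fraction of tiles carrying a true triplex-target insert
    decoy_insert_rate: float = 0.40     # fraction carrying a decoy purine tract instead
    insert_mutation_rate: float = 0.08
    triplex_element_length: int = 45
    insert_flank_length: int = 500      # biased-composition flank next to every insert
    n_tfo_copies: int = 3
    n_repeat_families: int = 8
    repeat_consensus_length: int = 150
    repeat_rate: float = 0.05           # per-tile repeat-instance probability
    n_mirnas: int = 40
    track_noise_sd: float = 0.05
    #: mean geometric run length (tiles) of contiguous bound domains for
    #: the transcription-coupled mechanism, whose binding spreads along
    #: transcribed domains.  Runs give the interaction map the domain
    #: structure real maps show, i.e. label autocorrelation beyond what
    #: the features explain — the phenomenon block cross-validation exists
    #: to contain.  The other mechanisms bind punctately: triplex at
    #: single target tiles, the XOR pair at tile-level state
    #: co-occurrences, and noise lncRNAs by distance only.
    positive_run_length: float = 3.0
    #: optional named seed-group biases; miRNA seeds are drawn round-robin
    #: across groups (group recorded per seed).  None -> all from kmer_bias.
    seed_groups: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] | None = None

    def __post_init__(self) -> None:
        if self.chrom_length % self.tile_width:
            raise ValueError("chrom_length must be divisible by tile_width")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be > 0")
        if any(w < 0 for w in self.kmer_bias.values()):
            raise ValueError("kmer_bias weights must be >= 0")
        object.__setattr__(self, "lncrnas", tuple(self.lncrnas))

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class SyntheticGenome:
    tiling: TiledGenome
    sequences: dict[str, np.ndarray]          # chrom -> int8 base codes
    genes: dict[str, tuple[str, int, int]]    # lncRNA -> (chrom, start, end)
    transcripts: dict[str, str]
    repeat_consensus: dict[str, str]
    repeat_instances: list[tuple[str, int, int, str]]  # chrom, start, end, family
    mirna_seeds: dict[str, str]
    mirna_groups: dict[str, str]
    triplex_element: str                      # config-wide element
    triplex_elements: dict[str, str]          # per-lncRNA elements (triplex mechanism)
    insert_tiles: dict[str, np.ndarray]       # chrom -> bool per tile

    def tile_sequence(self, chrom: str, tile_index: int, width: int) -> str:
        codes = self.sequences[chrom][tile_index * width:(tile_index + 1) * width]
        return _BASE_ARR[codes].tobytes().decode("ascii")

    def fasta_records(self):
        for chrom, codes in self.sequences.items():
            yield chrom, _BASE_ARR[codes].tobytes().decode("ascii")


@dataclass
class SyntheticTracks:
    """Per-tile context signals plus the latents that drive labels."""

    values: dict[str, dict[str, np.ndarray]]   # track -> chrom -> per-tile values
    latents: dict[str, dict[str, np.ndarray]]  # latent -> chrom -> per-tile values
    family_of_track: dict[str, str]


def _sample_kmer_chain(rng: np.random.Generator, bias: dict[str, float],
                       length: int, kmers: list[str] | None = None) -> str:
    """Concatenate 5-mers drawn proportionally to the bias weights."""
    if kmers is None:
        kmers = sorted(bias) if bias else list(canonical_kmers(5))
    w = np.array([bias.get(km, 1.0) for km in kmers], dtype=float)
    w = w / w.sum()
    n = length // 5 + 1
    idx = rng.choice(len(kmers), size=n, p=w)
    return "".join(kmers[i] for i in idx)[:length]


def _mixed_sequence(rng: np.random.Generator, bias: dict[str, float],
                    length: int, biased_fraction: float) -> str:
    """Alternating biased-chain and uniform segments, `length` nt total."""
    parts = []
    pos = 0
    seg = 50
    while pos < length:
        ln = min(seg, length - pos)
        if rng.random() < biased_fraction and bias:
            parts.append(_sample_kmer_chain(rng, bias, ln))
        else:
            parts.append(_BASE_ARR[rng.integers(0, 4, ln)].tobytes().decode())
        pos += ln
    return "".join(parts)


def generate_genome(cfg: SyntheticConfig) -> SyntheticGenome:
    """Genome sequences, annotations and sequence resources for a config."""
    rng = np.random.default_rng(cfg.seed)
    tiling = tile_genome(cfg.chrom_sizes(), cfg.tile_width)
    # gene placement validation
    by_chrom: dict[str, list[LncSpec]] = {}
    for spec in cfg.lncrnas:
        if spec.chrom not in cfg.chrom_names:
            raise ValueError(f"unknown chromosome {spec.chrom!r}")
        if spec.gene_end > cfg.chrom_length:
            raise ValueError(f"gene of {spec.name} exceeds chromosome")
        by_chrom.setdefault(spec.chrom, []).append(spec)
    for chrom, specs in by_chrom.items():
        ivs = sorted((s.gene_start, s.gene_end) for s in specs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping gene intervals on {chrom}")

    sequences = {c: rng.integers(0, 4, cfg.chrom_length, dtype=np.int8)
                 for c in cfg.chrom_names}

    # triplex elements: purine tracts drawn from the bias restricted to
    # all-purine 5-mers (uniform purines when no bias is set).  One
    # config-wide element, plus a per-lncRNA element for each triplex
    # lncRNA (its own bias if set), which is the one inserted on its
    # chromosome.
    purine_kmers = [km for km in canonical_kmers(5) if set(km) <= {"A", "G"}]
    element = _sample_kmer_chain(rng, {}, cfg.triplex_element_length,
                                 kmers=purine_kmers)
    triplex_elements: dict[str, str] = {}
    for spec in cfg.lncrnas:
        if spec.mechanism == "triplex":
            bias = dict(spec.kmer_bias) if spec.kmer_bias is not None else {}
            triplex_elements[spec.name] = _sample_kmer_chain(
                rng, bias, cfg.triplex_element_length, kmers=purine_kmers)
    element_of_chrom = {c: element for c in cfg.chrom_names}
    for spec in cfg.lncrnas:
        if spec.mechanism == "triplex" and element_of_chrom[spec.chrom] is element:
            element_of_chrom[spec.chrom] = triplex_elements[spec.name]

    # plant purine-tract inserts in random tiles.  A *true* insert is a
    # mutated copy of the chromosome's triplex element; a *decoy* insert is
    # a fresh random purine chain of the same length.  Both carry the same
    # biased-composition flank.  At the 5-mer level true and decoy tiles
    # are nearly indistinguishable (both purine tracts + shared flank
    # vocabulary), but only true inserts match the lncRNA's triplex-forming
    # oligos, so the triplex quartet carries cleaner label information than
    # any k-mer summary — while bound tiles still share 5-mer content with
    # the lncRNA transcripts broadly (flank + transcript draw from the same
    # bias), which is what the rank/density correlation analyses exploit.
    purine_kmer_list = purine_kmers
    insert_tiles: dict[str, np.ndarray] = {}
    for chrom in cfg.chrom_names:
        el_codes = np.searchsorted(
            _BASE_ARR, np.frombuffer(element_of_chrom[chrom].encode(), dtype=np.uint8))
        n_tiles = tiling.chrom_tile_count(chrom)
        u = rng.random(n_tiles)
        true_flags = u < cfg.insert_rate
        decoy_flags = (~true_flags) & (u < cfg.insert_rate + cfg.decoy_insert_rate)
        insert_tiles[chrom] = true_flags
        ins_len = len(el_codes) + cfg.insert_flank_length
        for ti in np.nonzero(true_flags | decoy_flags)[0]:
            if true_flags[ti]:
                copy = el_codes.copy()
                mut = rng.random(len(copy)) < cfg.insert_mutation_rate
                copy[mut] = rng.integers(0, 4, int(mut.sum()))
            else:
                decoy = _sample_kmer_chain(rng, {}, cfg.triplex_element_length,
                                           kmers=purine_kmer_list)
                copy = np.searchsorted(_BASE_ARR,
                                       np.frombuffer(decoy.encode(), dtype=np.uint8))
            if cfg.insert_flank_length:
                flank = _sample_kmer_chain(rng, cfg.kmer_bias, cfg.insert_flank_length)
                fl_codes = np.searchsorted(
                    _BASE_ARR, np.frombuffer(flank.encode(), dtype=np.uint8))
                copy = np.concatenate([copy, fl_codes])
            off = int(rng.integers(0, cfg.tile_width - ins_len))
            sequences[chrom][ti * cfg.tile_width + off:
                             ti * cfg.tile_width + off + len(copy)] = copy

    # lncRNA transcripts: biased-chain mixtures; triplex lncRNAs carry TFO
    # copies of their element
    genes = {}
    transcripts = {}
    for spec in cfg.lncrnas:
        genes[spec.name] = (spec.chrom, spec.gene_start, spec.gene_end)
        bias = dict(spec.kmer_bias) if spec.kmer_bias is not None else cfg.kmer_bias
        seq = _mixed_sequence(rng, bias, cfg.transcript_length, cfg.biased_fraction)
        if spec.mechanism == "triplex":
            el = triplex_elements[spec.name]
            seq = list(seq)
            gap = cfg.transcript_length // (cfg.n_tfo_copies + 1)
            for i in range(cfg.n_tfo_copies):
                pos = gap * (i + 1)
                seq[pos:pos + len(el)] = el
            seq = "".join(seq)[:cfg.transcript_length]
        transcripts[spec.name] = seq

    repeat_consensus = {
        f"rep{f:02d}": _mixed_sequence(rng, cfg.kmer_bias,
                                       cfg.repeat_consensus_length, cfg.biased_fraction)
        for f in range(cfg.n_repeat_families)}
    families = sorted(repeat_consensus)
    repeat_instances = []
    for chrom in cfg.chrom_names:
        n_tiles = tiling.chrom_tile_count(chrom)
        hit = np.nonzero(rng.random(n_tiles) < cfg.repeat_rate)[0]
        fams = rng.integers(0, len(families), len(hit))
        offs = rng.integers(0, cfg.tile_width - cfg.repeat_consensus_length, len(hit))
        for ti, fi, off in zip(hit, fams, offs):
            start = int(ti) * cfg.tile_width + int(off)
            repeat_instances.append((chrom, start, start + cfg.repeat_consensus_length,
                                     families[int(fi)]))

    mirna_seeds = {}
    mirna_groups = {}
    if cfg.seed_groups is not None:
        groups = [(name, dict(bias)) for name, bias in cfg.seed_groups]
    else:
        groups = [("main", cfg.kmer_bias)]
    for i in range(cfg.n_mirnas):
        gname, gbias = groups[i % len(groups)]
        mirna_seeds[f"mir{i:03d}"] = _sample_kmer_chain(rng, gbias, 7)
        mirna_groups[f"mir{i:03d}"] = gname

    return SyntheticGenome(tiling, sequences, genes, transcripts, repeat_consensus,
                           repeat_instances, mirna_seeds, mirna_groups,
                           element, triplex_elements, insert_tiles)


def _block_latent(rng: np.random.Generator, n_tiles: int, mean_block_tiles: float) -> np.ndarray:
    """Piecewise-constant signal with geometric block lengths."""
    p = min(1.0, 1.0 / max(mean_block_tiles, 1e-9))
    change = rng.random(n_tiles) < p
    change[0] = True
    block_id = np.cumsum(change) - 1
    values = rng.normal(size=int(block_id[-1]) + 1)
    return values[block_id]


DEFAULT_TRACK_LAYOUT = {
    # track name -> (latent name, family)
    "gro_like": ("transcription", "transcription"),
    "polii_like": ("transcription", "transcription"),
    "meth": ("methylation", "methylation"),
    "chrom_mark": ("chromatin", "chromatin"),
}


def generate_context_tracks(cfg: SyntheticConfig, genome: SyntheticGenome,
                            layout: dict[str, tuple[str, str]] | None = None) -> SyntheticTracks:
    """Spatially autocorrelated per-tile context tracks.

    Each track is its latent plus i.i.d. noise; tracks sharing a latent form
    one family.  The 'transcription' latent drives labels for
    mechanism=transcription lncRNAs; the 'methylation' and 'chromatin'
    latents form the XOR pair for mechanism=xor_pair lncRNAs.
    """
    layout = layout or DEFAULT_TRACK_LAYOUT
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    mean_block = cfg.track_block_length / cfg.tile_width
    latent_names = sorted({ln for ln, _fam in layout.values()})
    latents = {ln: {c: _block_latent(rng, genome.tiling.chrom_tile_count(c), mean_block)
                    for c in cfg.chrom_names}
               for ln in latent_names}
    values = {}
    family_of = {}
    for track, (latent, family) in layout.items():
        family_of[track] = family
        values[track] = {c: latents[latent][c] +
                         cfg.track_noise_sd * rng.normal(size=len(latents[latent][c]))
                         for c in cfg.chrom_names}
    return SyntheticTracks(values, latents, family_of)


def xor_indicator(tracks: SyntheticTracks, chrom: str,
                  latent_a: str = "methylation", latent_b: str = "chromatin") -> np.ndarray:
    """Tile-level XOR of the two latents after median thresholding."""
    a = tracks.latents[latent_a][chrom]
    b = tracks.latents[latent_b][chrom]
    return (a > np.median(a)) ^ (b > np.median(b))


def _planted_signal(spec: LncSpec, genome: SyntheticGenome,
                    tracks: SyntheticTracks) -> np.ndarray | None:
    """Per-tile planted binary signal on the lncRNA's chromosome."""
    chrom = spec.chrom
    if spec.mechanism == "noise":
        return None
    if spec.mechanism == "transcription":
        lat = tracks.latents["transcription"][chrom]
        return lat > np.median(lat)
    if spec.mechanism == "triplex":
        return genome.insert_tiles[chrom].copy()
    if spec.mechanism == "xor_pair":
        return xor_indicator(tracks, chrom)
    raise AssertionError(spec.mechanism)


def generate_interactions(cfg: SyntheticConfig, genome: SyntheticGenome,
                          tracks: SyntheticTracks) -> InteractionMap:
    """Sample each lncRNA's bound tiles from the planted binding law.

    p(tile) prop-to exp(-d/decay) * sigmoid(effect * (2b - 1)) with b the
    planted binary signal; noise lncRNAs use distance only.  Sampling is
    without replacement (exponential keys) until ``n_target_positives``.

    Track-driven mechanisms bind in contiguous domains: seed tiles drawn
    from the law above are extended into geometric runs of mean
    ``positive_run_length`` tiles.  Triplex binding is site-specific (one
    target tile per insert), so no runs there.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    tiling = genome.tiling
    lncrnas = {}
    bound = {}
    for spec in cfg.lncrnas:
        chrom = spec.chrom
        tiles = tiling.chrom_tile_ids(chrom)
        n_target = spec.n_target_positives
        if n_target > len(tiles):
            raise ValueError(f"{spec.name}: n_target_positives exceeds tiles on {chrom}")
        d = tiling.gene_distances(tiles, chrom, spec.gene_start, spec.gene_end)
        p = np.exp(-d / cfg.decay_scale)
        sig = _planted_signal(spec, genome, tracks)
        if sig is not None:
            s = 2.0 * sig - 1.0
            p = p / (1.0 + np.exp(-spec.effect_size * s))
        keys = -np.log(rng.random(len(tiles))) / p
        order = np.argsort(keys, kind="stable")
        run_mean = (cfg.positive_run_length
                    if spec.mechanism == "transcription" else 1.0)
        if run_mean <= 1.0:
            chosen = tiles[order[:n_target]]
        else:
            taken: set[int] = set()
            q = 1.0 / run_mean
            for idx in order:
                if len(taken) >= n_target:
                    break
                if int(tiles[idx]) in taken:
                    continue
                run = int(rng.geometric(q))  # total run length, mean = run_mean
                direction = 1 if rng.random() < 0.5 else -1
                for step in range(run):
                    jj = idx + direction * step
                    if jj < 0 or jj >= len(tiles) or len(taken) >= n_target:
                        break
                    taken.add(int(tiles[jj]))
            chosen = np.array(sorted(taken), dtype=np.int64)
        lncrnas[spec.name] = LncRNA(spec.name, chrom, spec.gene_start, spec.gene_end,
                                    genome.transcripts[spec.name])
        bound[spec.name] = np.sort(np.asarray(chosen))
    return InteractionMap(lncrnas, bound, tiling)
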