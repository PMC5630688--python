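"""Synthetic replicons with implanted genomic islands, plus truth records.

The generator embodies the premise of composition-based island detection:
every organism (and every mobile-element donor pool) has its own
oligonucleotide usage signature, and an acquired segment initially keeps
the donor's signature.

Host replicons are first-order chains with a strongly biased
mononucleotide composition and almost no higher-order structure: the
biased base composition spreads the tetranucleotide spectrum so that core
windows have stable word rankings (a low "noise floor" for the D
statistic), while the absence of higher-order structure keeps the
internally normalised variance RV near its sampling level, hence V near 1
in the core genome.

Donor models are log-tilts of the host composition with a fixed tilt
magnitude (the divergence knob): the donor's base frequencies are
``host_freqs * exp(divergence * u)``, renormalised, with the unit
direction ``u`` drawn near-orthogonal to the host's own log-composition
axis (tilts along that axis merely amplify the host's existing word
ranking instead of reordering it) and kept angularly separated between
donors.  Each donor additionally receives its own mild dinucleotide
structure so that donors with neighbouring tilt directions remain
distinguishable.  These defaults were calibrated once so that, at the
package's default thresholds, implanted islands are detectable and island
families from one donor stay above the similarity floor while different
donors stay well below it.

Islands are donor-sampled segments spliced into the host, optionally
split into several fragments and optionally "ameliorated" by point
substitutions drawn from the host's base composition.  Everything is
reproducible from (spec, seed); truth files use 1-based inclusive
coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CompositionModel",
    "Implant",
    "TruthRecord",
    "CorpusSpec",
    "SimGenome",
    "Corpus",
    "random_host_model",
    "donor_models",
    "tilted_model",
    "sample_genome",
    "implant",
    "make_corpus",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Calibrated divergence knobs (see module docstring and docs/methods.md).
HOST_BASE_CONCENTRATION = 7.0     # spread of host base compositions
HOST_ROW_CONCENTRATION = 3000.0   # host higher-order structure (high = almost none)
DONOR_DIVERGENCE = 1.1            # fixed log-tilt magnitude of donor compositions
DONOR_ROW_CONCENTRATION = 150.0   # donor dinucleotide individuality
_HOST_AXIS_MAX_COS = 0.22         # donor tilts stay near-orthogonal to host axis
_PAIRWISE_MAX_COS = 0.85          # angular separation between donor tilts


@dataclass(frozen=True)
class CompositionModel:
    """Order-0 or order-1 nucleotide model over ACGT."""

    id: str
    order: int
    mono: np.ndarray | None = None     # order 0: base frequencies
    trans: np.ndarray | None = None    # order 1: 4x4 row-stochastic matrix

    def __post_init__(self):
        if self.order == 0:
            if self.mono is None or abs(float(np.sum(self.mono)) - 1.0) > 1e-9:
                raise ValueError("order-0 model needs mono frequencies summing to 1")
            if np.any(np.asarray(self.mono) < 0):
                raise ValueError("negative probability")
        elif self.order == 1:
            t = np.asarray(self.trans, dtype=float) if self.trans is not None else None
            if t is None or t.shape != (4, 4):
                raise ValueError("order-1 model needs a 4x4 transition matrix")
            if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("transition rows must be non-negative and sum to 1")
        else:
            raise ValueError("order must be 0 or 1")

    def stationary(self) -> np.ndarray:
        """Stationary mononucleotide distribution."""
        if self.order == 0:
            return np.asarray(self.mono, dtype=float)
        vals, vecs = np.linalg.eig(np.asarray(self.trans).T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.abs(np.real(vecs[:, i]))
        return pi / pi.sum()

    def sample(self, length: int, rng: np.random.Generator) -> str:
        if length <= 0:
            raise ValueError("length must be positive")
        if self.order == 0:
            idx = rng.choice(4, size=length, p=np.asarray(self.mono, dtype=float))
            return _BASES[idx].tobytes().decode()
        cum = np.cumsum(np.asarray(self.trans, dtype=float), axis=1)
        cum[:, 3] = 1.0 + 1e-12
        rows = cum.tolist()
        u = rng.random(length).tolist()
        out = np.empty(length, dtype=np.uint8)
        s = int(rng.choice(4, p=self.stationary()))
        bases = _BASES
        for t in range(length):
            row = rows[s]
            x = u[t]
            if x < row[0]:
                s = 0
            elif x < row[1]:
                s = 1
            elif x < row[2]:
                s = 2
            else:
                s = 3
            out[t] = bases[s]
        return out.tobytes().decode()


# ---------------------------------------------------------------------------
# model generators
# ---------------------------------------------------------------------------

def random_host_model(
    model_id: str,
    rng: np.random.Generator,
    base_concentration: float = HOST_BASE_CONCENTRATION,
    row_concentration: float = HOST_ROW_CONCENTRATION,
) -> CompositionModel:
    """Host replicon model: strongly biased base composition (each base
    frequency kept within [0.10, 0.45]), near-zero higher-order structure."""
    base = rng.dirichlet(np.full(4, base_concentration))
    # real replicons have a clear composition bias; near-uniform hosts have a
    # flat word spectrum whose noisy rankings would inflate the D noise floor
    while base.min() < 0.10 or base.max() > 0.45 or base.max() - base.min() < 0.15:
        base = rng.dirichlet(np.full(4, base_concentration))
    trans = np.vstack([rng.dirichlet(row_concentration * base) for _ in range(4)])
    return CompositionModel(id=model_id, order=1, trans=trans)


def _unit_tilt(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(4)
    v -= v.mean()
    return v / np.linalg.norm(v)


def _host_axis(host: CompositionModel) -> np.ndarray:
    lp = np.log(host.stationary())
    lp -= lp.mean()
    return lp / np.linalg.norm(lp)


def spread_tilt_directions(
    rng: np.random.Generator,
    n: int,
    host: CompositionModel,
    pairwise_max_cos: float = _PAIRWISE_MAX_COS,
    host_axis_max_cos: float = _HOST_AXIS_MAX_COS,
    max_tries: int = 200_000,
) -> list[np.ndarray]:
    """Rejection-sample ``n`` unit tilt directions that avoid the host's
    log-composition axis and keep pairwise angular separation."""
    axis = _host_axis(host)
    dirs: list[np.ndarray] = []
    for _ in range(max_tries):
        u = _unit_tilt(rng)
        if abs(float(u @ axis)) <= host_axis_max_cos and all(
            float(u @ w) < pairwise_max_cos for w in dirs
        ):
            dirs.append(u)
            if len(dirs) == n:
                return dirs
    raise RuntimeError(f"could only place {len(dirs)}/{n} tilt directions")


def tilted_model(
    model_id: str,
    parent: CompositionModel,
    rng: np.random.Generator,
    direction: np.ndarray | None = None,
    divergence: float = DONOR_DIVERGENCE,
    row_concentration: float = DONOR_ROW_CONCENTRATION,
) -> CompositionModel:
    """Donor model: fixed-magnitude log-tilt of the parent composition plus
    mild individual dinucleotide structure."""
    u = direction if direction is not None else _unit_tilt(rng)
    b = parent.stationary() * np.exp(divergence * np.asarray(u, dtype=float))
    b /= b.sum()
    trans = np.vstack(
        [rng.dirichlet(np.maximum(row_concentration * b, 1e-3)) for _ in range(4)]
    )
    return CompositionModel(id=model_id, order=1, trans=trans)


def donor_models(
    n: int,
    host: CompositionModel,
    rng: np.random.Generator,
    divergence: float = DONOR_DIVERGENCE,
    row_concentration: float = DONOR_ROW_CONCENTRATION,
) -> list[CompositionModel]:
    """A pool of ``n`` mutually distinguishable donor models around ``host``."""
    dirs = spread_tilt_directions(rng, n, host)
    return [
        tilted_model(f"donor{j:02d}", host, rng, dirs[j], divergence, row_concentration)
        for j in range(n)
    ]


def sample_genome(model: CompositionModel, length: int, seed: int) -> str:
    """Reproducible sequence of exactly ``length`` bases from ``model``."""
    rng = np.random.default_rng(seed)
    return model.sample(length, rng)


# ---------------------------------------------------------------------------
# implantation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Implant:
    start: int              # 0-based half-open, in the final sequence
    end: int
    donor_model_id: str
    n_fragments: int
    mutation_rate: float


@dataclass
class TruthRecord:
    genome_id: str
    implants: list[Implant] = field(default_factory=list)
    lineage: str = ""


def _mutate(segment: str, rate: float, host_mono: np.ndarray, rng: np.random.Generator) -> str:
    """Point substitutions at ``rate`` per site, replacements drawn from the
    host base composition (amelioration pulls the insert toward the host)."""
    if rate <= 0:
        return segment
    arr = np.frombuffer(segment.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        arr[hit] = _BASES[rng.choice(4, size=n, p=host_mono)]
    return arr.tobytes().decode()


def implant(
    host_sequence: str,
    donor_model: CompositionModel,
    island_len: int,
    seed: int,
    n_fragments: int = 1,
    spacing: int = 10000,
    mutation_rate: float = 0.0,
    positions: list[int] | None = None,
    host_mono: np.ndarray | None = None,
) -> tuple[str, list[Implant]]:
    """Insert a donor-sampled island (optionally split into fragments).

    One segment of ``island_len`` is sampled from the donor, cut into
    ``n_fragments`` near-equal pieces and spliced into the host at
    positions separated by at least ``spacing`` (random unless given).
    Returns the new sequence and implant records with coordinates in the
    final sequence.
    """
    rng = np.random.default_rng(seed)
    if island_len < 1000:
        raise ValueError("island_len must be >= 1 kb")
    L = len(host_sequence)
    if (n_fragments + 1) * spacing >= L:
        raise ValueError("fragments and spacing do not fit in the host")

    segment = donor_model.sample(island_len, rng)
    if mutation_rate > 0:
        mono = host_mono if host_mono is not None else np.full(4, 0.25)
        segment = _mutate(segment, mutation_rate, np.asarray(mono, dtype=float), rng)

    bounds = np.linspace(0, island_len, n_fragments + 1).astype(int)
    pieces = [segment[bounds[i] : bounds[i + 1]] for i in range(n_fragments)]

    if positions is None:
        lo, hi = spacing, L - spacing
        pts = np.sort(rng.choice(np.arange(lo, hi), size=n_fragments, replace=False))
        while n_fragments > 1 and np.min(np.diff(pts)) < spacing:
            pts = np.sort(rng.choice(np.arange(lo, hi), size=n_fragments, replace=False))
        positions = [int(p) for p in pts]
    if sorted(positions) != list(positions):
        raise ValueError("positions must be sorted")

    chunks: list[str] = []
    implants: list[Implant] = []
    prev = 0
    offset = 0
    for piece, pos in zip(pieces, positions):
        chunks.append(host_sequence[prev:pos])
        start = pos + offset
        chunks.append(piece)
        implants.append(
            Implant(
                start=start,
                end=start + len(piece),
                donor_model_id=donor_model.id,
                n_fragments=n_fragments,
                mutation_rate=mutation_rate,
            )
        )
        offset += len(piece)
        prev = pos
    chunks.append(host_sequence[prev:])
    return "".join(chunks), implants


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusSpec:
    """Study conditions for the default synthetic corpus.

    30 replicons of 300 kb, 10 donor models shared across the corpus,
    10 implanted islands of 10 kb per replicon (donor j on island slot j,
    so each donor founds a 30-member island family), no amelioration by
    default.  A configurable fraction of implants carries mobile-element
    keyword annotations so keyword confirmation is exercisable.
    """

    n_genomes: int = 30
    genome_length: int = 300_000
    n_donor_models: int = 10
    islands_per_genome: int = 10
    island_length: int = 10_000
    mutation_rate: float = 0.0
    keyword_fraction: float = 0.5
    host_base_concentration: float = HOST_BASE_CONCENTRATION
    host_row_concentration: float = HOST_ROW_CONCENTRATION
    donor_divergence: float = DONOR_DIVERGENCE
    donor_row_concentration: float = DONOR_ROW_CONCENTRATION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown corpus spec keys: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        if self.n_genomes < 1 or self.n_donor_models < 1:
            raise ValueError("need at least one genome and one donor model")
        occupied = self.islands_per_genome * (self.island_length + 2000)
        if occupied >= self.genome_length:
            raise ValueError("islands do not fit in the genome at this length")


_MGE_PRODUCTS = [
    "putative phage integrase",
    "IS-element transposase",
    "conjugal transfer protein",
    "site-specific recombinase",
]


@dataclass
class SimGenome:
    id: str
    sequence: str
    model: CompositionModel
    truth: TruthRecord
    # features: (start, end, strand, type, product), 0-based half-open
    features: list[tuple[int, int, str, str, str]] = field(default_factory=list)


@dataclass
class Corpus:
    spec: CorpusSpec
    genomes: list[SimGenome]
    donors: list[CompositionModel]

    def island_sequences(self) -> dict[str, tuple[str, str, str]]:
        """island id -> (genome_id, donor_id, sequence) for every true implant."""
        out = {}
        for g in self.genomes:
            for k, imp in enumerate(g.truth.implants):
                iid = f"{g.id}.i{k:02d}"
                out[iid] = (g.id, imp.donor_model_id, g.sequence[imp.start : imp.end])
        return out


def _lineage(i: int) -> str:
    """Nested synthetic taxonomy: strains pair into species, species into
    genera, and so on up a binary hierarchy (one shared phylum/domain)."""
    return ";".join(
        [
            f"Domain{i // 64}",
            f"Phylum{i // 32}",
            f"Order{i // 16}",
            f"Family{i // 8}",
            f"Genus{i // 4}",
            f"species{i // 2}",
            f"strain{i:02d}",
        ]
    )


def make_corpus(
    spec: CorpusSpec | None = None, seed: int = 0, out_dir: str | Path | None = None
) -> Corpus:
    """Build (and optionally write) the synthetic corpus.

    All replicons share one host composition family (mild per-genome
    variation) so that corpus-wide island families are defined by the
    donors alone.  Deterministic for a given (spec, seed).  When
    ``out_dir`` is given, writes per-genome FASTA + GenBank, a truth TSV
    and a lineage TSV (1-based inclusive coordinates in files).
    """
    spec = spec or CorpusSpec()
    spec.validate()
    master = np.random.default_rng(seed)

    base_host = random_host_model(
        "host_base", master, spec.host_base_concentration, spec.host_row_concentration
    )
    dirs = spread_tilt_directions(master, spec.n_donor_models, base_host)
    donors = [
        tilted_model(
            f"donor{j:02d}",
            base_host,
            master,
            dirs[j],
            spec.donor_divergence,
            spec.donor_row_concentration,
        )
        for j in range(spec.n_donor_models)
    ]

    genomes: list[SimGenome] = []
    for i in range(spec.n_genomes):
        gid = f"SYNG{i:03d}"
        host = tilted_model(
            f"host_{gid}",
            base_host,
            master,
            direction=np.zeros(4),
            divergence=0.0,
            row_concentration=spec.host_row_concentration,
        )
        seq = host.sample(spec.genome_length, master)
        host_mono = host.stationary()

        n_isl = spec.islands_per_genome
        truth = TruthRecord(genome_id=gid, lineage=_lineage(i))
        features: list[tuple[int, int, str, str, str]] = []
        if n_isl > 0:
            block = spec.genome_length // n_isl
            positions = [
                int(j * block + master.integers(block // 4, 3 * block // 4))
                for j in range(n_isl)
            ]
            offset = 0
            chunks: list[str] = []
            prev = 0
            for j, pos in enumerate(positions):
                donor = donors[j % spec.n_donor_models]
                rng_piece = np.random.default_rng(int(master.integers(2**31)))
                piece = donor.sample(spec.island_length, rng_piece)
                if spec.mutation_rate > 0:
                    piece = _mutate(piece, spec.mutation_rate, host_mono, rng_piece)
                chunks.append(seq[prev:pos])
                start = pos + offset
                truth.implants.append(
                    Implant(start, start + len(piece), donor.id, 1, spec.mutation_rate)
                )
                keyword = master.random() < spec.keyword_fraction
                product = (
                    _MGE_PRODUCTS[j % len(_MGE_PRODUCTS)]
                    if keyword
                    else "hypothetical protein"
                )
                mid = start + len(piece) // 2
                features.append((mid - 450, mid + 450, "+", "CDS", product))
                chunks.append(piece)
                offset += len(piece)
                prev = pos
            chunks.append(seq[prev:])
            seq = "".join(chunks)
        genomes.append(SimGenome(gid, seq, host, truth, features))

    corpus = Corpus(spec=spec, genomes=genomes, donors=donors)
    if out_dir is not None:
        _write_corpus(corpus, Path(out_dir))
    return corpus


def _write_corpus(corpus: Corpus, out: Path) -> None:
    from . import io as iomod

    out.mkdir(parents=True, exist_ok=True)
    truth_rows = ["genome\tstart\tend\tdonor\tn_fragments\tmutation_rate"]
    lineage_rows = ["genome\tlineage"]
    for g in corpus.genomes:
        rec = iomod.RepliconRecord(
            accession=g.id,
            description=f"synthetic replicon {g.id}",
            sequence=g.sequence,
            features=[iomod.Feature(*f) for f in g.features],
            lineage=g.truth.lineage,
        )
        iomod.write_fasta(rec, out / f"{g.id}.fasta")
        iomod.write_genbank(rec, out / f"{g.id}.gbk")
        for imp in g.truth.implants:
            truth_rows.append(
                f"{g.id}\t{imp.start + 1}\t{imp.end}\t{imp.donor_model_id}"
                f"\t{imp.n_fragments}\t{imp.mutation_rate}"
            )
        lineage_rows.append(f"{g.id}\t{g.truth.lineage}")
    (out / "truth.tsv").write_text("\n".join(truth_rows) + "\n")
    (out / "lineages.tsv").write_text("\n".join(lineage_rows) + "\n")
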