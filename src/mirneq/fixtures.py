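"""Synthetic miRNA/mRNA generator with planted target sites.

Every stage of the predictor is tested against sequences whose ground truth is
known by construction: an mRNA is a non-pairing poly-A background with an
insert at a chosen offset.  The insert is the exact reverse complement of the
miRNA (``perfect``), a complement carrying exactly one GU wobble opposite a
seed position (``seed_gu``), a seed-complement-only insert whose remaining
positions cannot pair (``seed_only``), or a dinucleotide-preserving shuffle of
the complement that the scanner verifiably reports nothing for
(``scrambled``).  The ``hairpin_occluded`` context additionally plants the
miRNA sequence itself downstream of the site so the mRNA folds into a long
helix covering the site, making the opening cost large.

miRNAs are sampled with moderate GC content, no poly-A runs (which would pair
with the background), and at least one G/U in the seed so a wobble variant
always exists.  Generation is a pure function of the spec: identical specs
give identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._seq import reverse_complement
from .duplex_scan import scan_candidate_sites
from .energy_params import EnergyParameterSet, load_parameters

__all__ = ["FixtureSpec", "make_fixture", "dinucleotide_shuffle", "write_fixture_files"]

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
#: a base guaranteed not to pair with the given miRNA base (for seed_only filler)
_NONPAIRING = {"A": "A", "C": "A", "G": "A", "U": "C"}


@dataclass(frozen=True)
class FixtureSpec:
    rng_seed: int
    mrna_length: int = 80
    site_offset: int = 30
    mirna_length: int = 22
    site_kind: str = "perfect"  # perfect | seed_only | seed_gu | scrambled
    context: str = "unstructured"  # unstructured | hairpin_occluded

    def __post_init__(self) -> None:
        if self.site_kind not in ("perfect", "seed_only", "seed_gu", "scrambled"):
            raise ValueError(f"unknown site kind {self.site_kind!r}")
        if self.context not in ("unstructured", "hairpin_occluded"):
            raise ValueError(f"unknown context {self.context!r}")
        if not (15 <= self.mirna_length <= 30):
            raise ValueError("miRNA length must be 15-30 nt")
        if self.site_offset < 0 or self.site_offset + self.mirna_length > self.mrna_length:
            raise ValueError("site does not fit inside the mRNA")


def _sample_mirna(rng: np.random.Generator, length: int) -> str:
    """Random miRNA with >= 35% GC, no AAAA run, and a G/U in the seed."""
    for _ in range(10_000):
        seq = "".join(rng.choice(_BASES, size=length))
        gc = seq.count("G") + seq.count("C")
        if gc < max(1, round(0.35 * length)):
            continue
        if "AAAA" in seq:
            continue
        if not set(seq[1:7]) & {"G", "U"}:
            continue
        return seq
    raise RuntimeError("miRNA sampling failed to satisfy constraints")


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Eulerian-walk resampling).

    Consecutive-character edges form a multigraph; a random Eulerian path with
    the original first and last characters is drawn by shuffling adjacency
    lists and retrying until the greedy walk consumes every edge.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    for _ in range(10_000):
        adj = {v: list(rng.permutation(out)) for v, out in edges.items()}
        walk = [seq[0]]
        cur = seq[0]
        while adj.get(cur):
            cur = adj[cur].pop()
            walk.append(cur)
        if len(walk) == n_edges + 1:
            return "".join(walk)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")


def _build_site(mirna: str, kind: str, rng: np.random.Generator) -> str:
    comp = reverse_complement(mirna)
    L = len(mirna)
    if kind == "perfect":
        return comp
    if kind == "seed_gu":
        # one wobble opposite a seed position: G:C -> G:U or U:A -> U:G
        seed_idx = [i for i in range(1, 7) if mirna[i] in "GU"]
        pos = int(rng.choice(seed_idx))
        site = list(comp)
        site[L - 1 - pos] = "U" if mirna[pos] == "G" else "G"
        return "".join(site)
    if kind == "seed_only":
        site = [_NONPAIRING[b] for b in mirna[::-1]]
        for pos in range(1, 7):
            site[L - 1 - pos] = _COMPLEMENT[mirna[pos]]
        return "".join(site)
    raise ValueError(kind)  # scrambled is handled by the caller


def make_fixture(
    spec: FixtureSpec, params: EnergyParameterSet | None = None
) -> tuple[str, str, tuple[int, int]]:
    """Generate (miRNA, mRNA, ground-truth site interval) for ``spec``.

    For ``scrambled`` the insert is re-shuffled (deterministically, from the
    spec's seed) until the scanner reports no candidate site on the mRNA, so
    decoys are true negatives by construction, not merely by expectation.
    """
    rng = np.random.default_rng(spec.rng_seed)
    mirna = _sample_mirna(rng, spec.mirna_length)
    L = spec.mirna_length
    start, end = spec.site_offset, spec.site_offset + L
    tail_len = spec.mrna_length - end

    def assemble(insert: str) -> str:
        mrna = "A" * start + insert + "A" * tail_len
        if spec.context == "hairpin_occluded":
            # plant the miRNA sequence itself downstream: it zips up with the
            # site into a long helix, burying the site in structure
            mrna = mrna[:end] + "AAAA" + mirna + mrna[end:]
        return mrna

    if spec.site_kind == "scrambled":
        if params is None:
            params = load_parameters("default")
        comp = reverse_complement(mirna)
        for _ in range(100):
            insert = dinucleotide_shuffle(comp, rng)
            if insert == comp:
                continue
            mrna = assemble(insert)
            if not scan_candidate_sites(mirna, mrna, params):
                return mirna, mrna, (start, end)
        raise RuntimeError("could not build a site-free scrambled decoy")

    insert = _build_site(mirna, spec.site_kind, rng)
    return mirna, assemble(insert), (start, end)


def write_fixture_files(
    specs: list[FixtureSpec],
    mirna_fasta: str | Path,
    mrna_fasta: str | Path,
    truth_tsv: str | Path,
    params: EnergyParameterSet | None = None,
) -> None:
    """Write a fixture set as FASTA pair + ground-truth TSV (id, start, end, kind)."""
    mirna_lines, mrna_lines, truth = [], [], ["id\tstart\tend\tsite_kind"]
    for idx, spec in enumerate(specs):
        mirna, mrna, (start, end) = make_fixture(spec, params)
        name = f"fx{idx:04d}"
        mirna_lines += [f">{name}_mirna", mirna]
        mrna_lines += [f">{name}_mrna", mrna]
        truth.append(f"{name}\t{start}\t{end}\t{spec.site_kind}")
    Path(mirna_fasta).write_text("\n".join(mirna_lines) + "\n")
    Path(mrna_fasta).write_text("\n".join(mrna_lines) + "\n")
    Path(truth_tsv).write_text("\n".join(truth) + "\n")
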