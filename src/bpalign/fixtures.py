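"""Synthetic toy genome pairs for offline pipeline tests.

Builds a pair of ~1 kb circular "mitogenomes" related by a single planted
rearrangement:

* ``transposition`` -- one gene is cut out cleanly (no sequence gained or
  lost at the junctions) and pasted between two other genes, so every
  breakpoint region aligns flush.
* ``tdrl`` -- a two-gene block is duplicated in tandem and the redundant
  copies are lost, except that the first ``remnant_length`` nucleotides of
  one lost copy survive as a pseudogene remnant; the breakpoint between the
  genes upstream of the remnant then shows an overlap of exactly
  ``remnant_length`` nucleotides.

All sequences are synthetic (random under a fixed default seed); boundary
nucleotides at the planted junctions are adjusted so that chance matches
cannot extend the designed homology.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .breakpoints import GeneAnnotation
from .scoring import ALPHABET, NucSeq

GENES = ("nad1", "trnK", "cox2", "atp8", "trnD", "cob")

DEFAULT_SEED = 20430


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])


def _differ(base: str) -> str:
    """A fixed nucleotide different from ``base``."""
    return "A" if base != "A" else "C"


def _assemble(parts: list[tuple[str | None, str]]) -> tuple[str, list[GeneAnnotation]]:
    """Concatenate (gene_name_or_None, seq) parts into genome + annotation."""
    seq = ""
    anns = []
    for name, part in parts:
        if name is not None and part:
            anns.append(GeneAnnotation(name, len(seq) + 1, len(seq) + len(part), "+"))
        seq += part
    return seq, anns


def toy_genome_pair(
    kind: str,
    seed: int = DEFAULT_SEED,
    gene_length: int = 150,
    intergenic_length: int = 25,
    remnant_length: int = 12,
):
    """Build (ref_genome, ref_annotations, derived_genome, derived_annotations).

    ``kind`` is ``"transposition"`` or ``"tdrl"``; both derived genomes share
    the reference of the same seed.
    """
    if kind not in ("transposition", "tdrl"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)
    genes = {name: _rand_seq(rng, gene_length) for name in GENES}
    inter = [_rand_seq(rng, intergenic_length) for _ in GENES]

    ref_parts: list[tuple[str | None, str]] = []
    for idx, name in enumerate(GENES):
        ref_parts.append((name, genes[name]))
        ref_parts.append((None, inter[idx]))
    ref_seq, ref_anns = _assemble(ref_parts)

    g = list(GENES)
    if kind == "transposition":
        # cut gene g[2] exactly and paste it into the middle of intergenic 0:
        # derived order g0 g2 g1 g3 g4 g5
        h = intergenic_length // 2
        der_parts = [
            (g[0], genes[g[0]]),
            (None, inter[0][:h]),
            (g[2], genes[g[2]]),
            (None, inter[0][h:]),
            (g[1], genes[g[1]]),
            (None, inter[1]),
            (None, inter[2]),
            (g[3], genes[g[3]]),
            (None, inter[3]),
            (g[4], genes[g[4]]),
            (None, inter[4]),
            (g[5], genes[g[5]]),
            (None, inter[5]),
        ]
    else:
        # tandem duplication of the block (g3 inter3 g4) followed by losses:
        # copy one keeps only the first remnant_length nt of g3, copy two
        # loses g4 entirely -> derived order g0 g1 g2 g4 g3 g5 with a g3
        # pseudogene remnant in front of the moved g4
        d = remnant_length
        remnant = genes[g[3]][:d]
        # a chance match right after the remnant would extend the designed
        # overlap; force a mismatch at the first post-remnant position
        i3 = inter[3]
        i3 = _differ(genes[g[3]][d]) + i3[1:]
        der_parts = [
            (g[0], genes[g[0]]),
            (None, inter[0]),
            (g[1], genes[g[1]]),
            (None, inter[1]),
            (g[2], genes[g[2]]),
            (None, inter[2]),
            (None, remnant),
            (None, i3),
            (g[4], genes[g[4]]),
            (g[3], genes[g[3]]),
            (None, inter[3]),
            (None, inter[4]),
            (g[5], genes[g[5]]),
            (None, inter[5]),
        ]
    der_seq, der_anns = _assemble(der_parts)
    ref = NucSeq(f"ref_{kind}", ref_seq)
    der = NucSeq(f"derived_{kind}", der_seq)
    return ref, ref_anns, der, der_anns


def write_fixture_pair(outdir: str | Path, kind: str, seed: int = DEFAULT_SEED) -> dict:
    """Write one toy pair (FASTA + annotation TSV) and return manifest entry."""
    from .io import write_fasta  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, ref_anns, der, der_anns = toy_genome_pair(kind, seed=seed)
    paths = {}
    for label, genome, anns in (("ref", ref, ref_anns), ("derived", der, der_anns)):
        fa = outdir / f"{kind}_{label}.fa"
        tsv = outdir / f"{kind}_{label}.tsv"
        write_fasta([genome], fa)
        with open(tsv, "w") as fh:
            fh.write("#gene\tstart\tend\tstrand\n")
            for a in anns:
                fh.write(f"{a.gene}\t{a.start}\t{a.end}\t{a.strand}\n")
        # paths are kept relative to the manifest directory
        paths[label] = {"fasta": fa.name, "annotation": tsv.name, "circular": True}
    return {"id": kind, "reference": paths["ref"], "derived": paths["derived"]}


def write_fixture_manifest(outdir: str | Path, seed: int = DEFAULT_SEED) -> Path:
    """Write both toy pairs plus a pipeline manifest; return the manifest path."""
    outdir = Path(outdir)
    pairs = [write_fixture_pair(outdir, kind, seed) for kind in ("transposition", "tdrl")]
    manifest = {"flank": 60, "pairs": pairs}
    path = outdir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
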