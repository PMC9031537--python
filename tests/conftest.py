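import numpy as np
import pysam
import pytest

from asdetect import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small mixed-type simulated dataset shared across test modules."""
    cfg = SimConfig(n_genes=40, seed=3, genes_per_chrom=15)
    out_dir = tmp_path_factory.mktemp("sim_small")
    return simulate_dataset(cfg, str(out_dir))


@pytest.fixture(scope="session")
def sim_shallow(tmp_path_factory):
    """A shallow dataset (about 900 reads) for brute-force count oracles."""
    cfg = SimConfig(n_genes=12, seed=9, mean_depth=8.0, genes_per_chrom=12)
    out_dir = tmp_path_factory.mktemp("sim_shallow")
    return simulate_dataset(cfg, str(out_dir))


def write_sam(path, reads, chrom="chr1", length=100_000):
    """Write a minimal single-chromosome SAM file.

    ``reads`` are (name, pos, cigar_string, flag) tuples; sequences are
    synthesised as runs of 'A' matching the read length.
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, pos, cigar, flag in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            qlen = a.infer_query_length()
            a.query_sequence = "A" * qlen
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            out.write(a)
    return str(path)


@pytest.fixture
def sam_writer():
    return write_sam


def random_gene_annotation(rng, n_transcripts):
    """Random transcripts over a shared splice-site grid.

    Produces messy overlapping isoforms (retentions, skips, shifted sites)
    for comparing event extraction against a brute-force oracle.
    """
    from asdetect import Gene, GenomeAnnotation, Transcript

    n_sites = int(rng.integers(4, 9)) * 2
    sites = np.sort(rng.choice(np.arange(100, 5000, 20), n_sites, replace=False))
    transcripts = []
    for t in range(n_transcripts):
        # random walk over sites: alternate exon starts/ends, sometimes
        # skipping sites to create alternative boundaries and retentions
        exons = []
        i = int(rng.integers(0, 2))
        while i < n_sites - 1:
            j = i + 1 + int(rng.integers(0, min(3, n_sites - 1 - i)))
            exons.append((int(sites[i]), int(sites[j])))
            i = j + 1 + int(rng.integers(0, 3))
        if not exons:
            exons = [(int(sites[0]), int(sites[-1]))]
        transcripts.append(Transcript(id=f"t{t}", exons=tuple(exons)))
    gene = Gene(id="g1", seqname="c1", strand="+" if rng.random() < 0.5 else "-",
                transcripts=tuple(transcripts))
    return GenomeAnnotation(genes={"g1": gene})
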