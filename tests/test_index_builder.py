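import numpy as np
import pytest

from sigbloom import (
    CommunitySpec,
    GenomeRecord,
    build_index,
    generate_community,
    process_genome,
    read_index,
    reduce_signatures,
    write_index,
)
from sigbloom.hashing import HashFamily, extract_kmers
from sigbloom.index_builder import (
    DIRTY,
    IndexFormatError,
    IndexIntegrityError,
    SignatureIndex,
    entries_for_bytes,
    oracle_unique_kmers,
)
from sigbloom.query_engine import classify_kmer


def _fresh_index(genomes, m, n, k, omega=0, canonical=False, master_seed=0):
    family = HashFamily.from_master_seed(n=n, m=m, master_seed=master_seed)
    return SignatureIndex(
        entries=np.zeros(m, dtype=np.int32),
        k=k,
        family=family,
        genome_table=[(g.name, g.length) for g in genomes],
        phases_built=1,
        omega=omega,
        canonical=canonical,
    )


def _genome_kmers(genome, k, canonical):
    kmers = set()
    for seq in genome.sequences:
        kmers.update(m for _, m in extract_kmers(seq, k, canonical=canonical))
    return kmers


class TestProcessGenome:
    def test_single_genome_rehits_keep_gid(self):
        """Same-genome re-hits pass the uniqueness test, so after one pass
        every touched entry holds the gid — hand-traceable on 5 k-mers."""
        g = GenomeRecord(gid=1, name="g1", sequences=["ACGTACGT"])
        index = _fresh_index([g], m=64, n=1, k=4)
        process_genome(index, g, phase=1)
        touched = set()
        for _, kmer in extract_kmers("ACGTACGT", 4, canonical=False):
            touched.update(index.family.hash_kmer(kmer))
        assert touched  # the 5 windows hash somewhere
        assert all(index.entries[v] == 1 for v in touched)
        assert all(
            index.entries[v] == 0 for v in range(64) if v not in touched
        )

    def test_identical_genomes_total_collision(self):
        seq = "ACGTTGCAACGTAGGCATTTACGGA"
        g1 = GenomeRecord(gid=1, name="a", sequences=[seq])
        g2 = GenomeRecord(gid=2, name="b", sequences=[seq])
        index = _fresh_index([g1, g2], m=256, n=2, k=7)
        process_genome(index, g1, phase=1)
        process_genome(index, g2, phase=1)
        for _, kmer in extract_kmers(seq, 7, canonical=False):
            for v in index.family.hash_kmer(kmer):
                assert index.entries[v] == DIRTY

    def test_gid_outside_table_rejected(self, small_index, small_community):
        rogue = GenomeRecord(gid=99, name="zz", sequences=["ACGT" * 20])
        with pytest.raises(ValueError):
            process_genome(small_index, rogue, phase=1)

    def test_short_contig_contributes_nothing(self):
        g = GenomeRecord(gid=1, name="g1", sequences=["ACG"])
        index = _fresh_index([g], m=32, n=1, k=4)
        process_genome(index, g, phase=1)
        assert (index.entries == 0).all()

    def test_dirty_is_monotone_within_phase(self):
        """An entry that turns dirty never becomes positive again in the
        same phase (omega=0: only the main marking loop writes)."""
        genomes = generate_community(CommunitySpec.uniform(4, 800, seed=5))
        index = _fresh_index(genomes, m=512, n=2, k=11, canonical=True)
        for phase in (1, 2):
            dirty = set(np.nonzero(index.entries == DIRTY)[0])
            for g in genomes:
                process_genome(index, g, phase=phase)
                now = set(np.nonzero(index.entries == DIRTY)[0])
                assert dirty <= now
                dirty = now


class TestReduce:
    def _setup(self, omega):
        seq = "ACGTTGCAACGTAGGCATTTACGGAT"
        g = GenomeRecord(gid=1, name="g1", sequences=[seq])
        index = _fresh_index([g], m=128, n=2, k=5, omega=omega)
        process_genome(index, g, phase=1)
        return index, g

    def test_spacing_rule(self):
        index, g = self._setup(omega=10)
        selected = reduce_signatures(index, g, [0, 5, 20], omega=10)
        assert selected == [0, 20]
        # dropped k-mer dirtied, kept k-mers re-stamped
        for v in index.family.hash_kmer(g.sequences[0][5:10]):
            assert index.entries[v] == DIRTY
        for p in (0, 20):
            for v in index.family.hash_kmer(g.sequences[0][p : p + 5]):
                assert index.entries[v] == 1

    def test_single_position_kept(self):
        index, g = self._setup(omega=1000)
        before = index.entries.copy()
        assert reduce_signatures(index, g, [0], omega=1000) == [0]
        assert (index.entries == before).all()  # idempotent re-stamp only

    def test_omega_zero_keeps_strictly_increasing_positions(self):
        index, g = self._setup(omega=0)
        before = index.entries.copy()
        positions = [0, 1, 2, 7, 19]
        assert reduce_signatures(index, g, positions, omega=0) == positions
        assert (index.entries == before).all()

    def test_empty_positions_noop(self):
        index, g = self._setup(omega=5)
        assert reduce_signatures(index, g, [], omega=5) == []

    def test_built_with_omega_spacing_and_shrinkage(self):
        genomes = generate_community(CommunitySpec.uniform(3, 1500, seed=7))
        kwargs = dict(m=2**16, n=2, k=21, phases=2, master_seed=7)
        dense = build_index(genomes, omega=0, **kwargs)
        thin = build_index(genomes, omega=40, **kwargs)
        for gid, kept in thin.signature_positions.items():
            by_contig: dict[int, list[int]] = {}
            for ci, p in kept:
                by_contig.setdefault(ci, []).append(p)
            for plist in by_contig.values():
                assert all(b - a > 40 for a, b in zip(plist, plist[1:]))
            assert len(kept) <= len(dense.signature_positions[gid])
            # kept signature k-mers still classify to their genome
            g = genomes[gid - 1]
            for ci, p in kept:
                kmer = g.sequences[ci][p : p + 21]
                assert classify_kmer(thin, kmer) == gid


class TestBuildIndex:
    def test_single_genome_all_kmers_classify_home(self):
        g = generate_community(CommunitySpec.uniform(1, 1000, seed=3))
        index = build_index(g, m=2**15, n=2, k=21, phases=2, master_seed=3)
        for kmer in _genome_kmers(g[0], 21, True):
            assert classify_kmer(index, kmer) == 1

    def test_duplicate_names_rejected(self):
        g = GenomeRecord(gid=1, name="same", sequences=["ACGTACGTAC"])
        h = GenomeRecord(gid=2, name="same", sequences=["TTGCATTGCA"])
        with pytest.raises(ValueError):
            build_index([g, h], m=64, n=1, k=4)

    def test_tiny_m_may_be_all_dirty(self):
        genomes = generate_community(CommunitySpec.uniform(3, 500, seed=1))
        index = build_index(genomes, m=2, n=1, k=11, phases=2, master_seed=1)
        assert set(np.unique(index.entries)) <= {-1, 0, 1, 2, 3}

    def test_entry_values_legal(self, small_index):
        vals = np.unique(small_index.entries)
        assert set(vals.tolist()) <= set(range(-1, 6))

    def test_16bit_mode(self):
        genomes = generate_community(CommunitySpec.uniform(2, 600, seed=2))
        index = build_index(
            genomes, m=4096, n=2, k=15, phases=2, master_seed=2, entry_width=16
        )
        assert index.entries.dtype == np.int16
        for kmer in list(_genome_kmers(genomes[0], 15, True))[:50]:
            assert classify_kmer(index, kmer) in (-1, 0, 1, 2)


class TestOracle:
    def test_disjoint_footprints_all_unique(self):
        g1 = GenomeRecord(gid=1, name="a", sequences=["ACGTACGTTG"])
        g2 = GenomeRecord(gid=2, name="b", sequences=["TTGCATGGCA"])
        # search a master seed whose footprints happen to be disjoint
        for seed in range(50):
            fam = HashFamily.from_master_seed(n=2, m=2**20, master_seed=seed)
            f1 = {v for k in _genome_kmers(g1, 5, True) for v in fam.hash_kmer(k)}
            f2 = {v for k in _genome_kmers(g2, 5, True) for v in fam.hash_kmer(k)}
            if not (f1 & f2) and not (
                _genome_kmers(g1, 5, True) & _genome_kmers(g2, 5, True)
            ):
                break
        else:
            pytest.fail("no disjoint instance found")
        oracle = oracle_unique_kmers([g1, g2], fam, 5, canonical=True)
        assert set(oracle[1]) == _genome_kmers(g1, 5, True)
        assert set(oracle[2]) == _genome_kmers(g2, 5, True)

    def test_shared_kmer_unique_for_neither(self):
        shared = "ACGTACGTACGTACG"
        g1 = GenomeRecord(gid=1, name="a", sequences=[shared + "TTGCA"])
        g2 = GenomeRecord(gid=2, name="b", sequences=["GGCAT" + shared])
        fam = HashFamily.from_master_seed(n=2, m=2**20, master_seed=4)
        oracle = oracle_unique_kmers([g1, g2], fam, 15, canonical=True)
        canon = min(shared, shared.translate(str.maketrans("ACGT", "TGCA"))[::-1])
        assert canon not in oracle[1]
        assert canon not in oracle[2]

    def test_positions_reported(self):
        g = GenomeRecord(gid=1, name="a", sequences=["TTTTT"])
        fam = HashFamily.from_master_seed(n=1, m=2**16, master_seed=0)
        oracle = oracle_unique_kmers([g], fam, 3, canonical=True)
        assert oracle[1] == {"AAA": [(0, 0), (0, 1), (0, 2)]}


class TestOracleEquivalence:
    """The build's central correctness contract against the brute-force oracle.

    With a single hash function, classification equals the oracle exactly:
    dirty marks cannot leak across entries. With n >= 2, soundness stays
    exact (a k-mer classifying to g is always oracle-unique for g) while a
    small fraction of oracle-unique k-mers degrade to dirty through
    same-genome entry sharing with non-unique k-mers; they never degrade
    to absent or to a foreign genome.
    """

    def test_single_hash_exact_equivalence(
        self, small_community, single_hash_index
    ):
        oracle = oracle_unique_kmers(
            small_community, single_hash_index.family, 31, canonical=True
        )
        for g in small_community:
            unique = set(oracle[g.gid])
            for kmer in _genome_kmers(g, 31, True):
                call = classify_kmer(single_hash_index, kmer)
                assert (call == g.gid) == (kmer in unique)

    def test_multi_hash_soundness_and_dirty_only_gaps(
        self, small_community, small_index
    ):
        oracle = oracle_unique_kmers(
            small_community, small_index.family, 31, canonical=True
        )
        for g in small_community:
            unique = set(oracle[g.gid])
            for kmer in _genome_kmers(g, 31, True):
                call = classify_kmer(small_index, kmer)
                if call == g.gid:
                    assert kmer in unique
                elif kmer in unique:
                    assert call == DIRTY

    def test_phase1_first_genome_exact_last_genome_sound(self, small_community):
        index = build_index(
            small_community, m=2**16, n=2, k=31, phases=1, master_seed=11
        )
        oracle = oracle_unique_kmers(small_community, index.family, 31, True)
        first, last = small_community[0], small_community[-1]
        for kmer in _genome_kmers(first, 31, True):
            call = classify_kmer(index, kmer)
            assert (call == first.gid) == (kmer in oracle[first.gid])
        for kmer in _genome_kmers(last, 31, True):
            if classify_kmer(index, kmer) == last.gid:
                assert kmer in oracle[last.gid]

    def test_phase1_false_entries_removed_by_phase2(self, small_community):
        """Earlier genomes retain entries marking non-unique k-mers as their
        own after one pass; the second pass dirties every one of them."""
        one = build_index(
            small_community, m=2**16, n=2, k=31, phases=1, master_seed=11
        )
        two = build_index(
            small_community, m=2**16, n=2, k=31, phases=2, master_seed=11
        )
        oracle = oracle_unique_kmers(small_community, one.family, 31, True)
        g = small_community[0]
        covered = {
            v for kmer in oracle[g.gid] for v in one.family.hash_kmer(kmer)
        }
        false_marks = [
            v for v in np.nonzero(one.entries == g.gid)[0] if v not in covered
        ]
        assert false_marks, "expected phase-1 false entry marks for genome 1"
        assert all(two.entries[v] == DIRTY for v in false_marks)

    def test_phase2_permutation_invariance_single_hash(self, small_community):
        """With n=1 both orderings equal the oracle, hence each other."""
        perm = [small_community[i] for i in (2, 0, 4, 1, 3)]
        a = build_index(small_community, m=2**16, n=1, k=31, phases=2,
                        master_seed=11)
        b = build_index(perm, m=2**16, n=1, k=31, phases=2, master_seed=11)
        for g in small_community:
            gid_b = b.gid_of(g.name)
            for kmer in _genome_kmers(g, 31, True):
                ca, cb = classify_kmer(a, kmer), classify_kmer(b, kmer)
                ca_name = None if ca <= 0 else a.genome_table[ca - 1][0]
                cb_name = None if cb <= 0 else b.genome_table[cb - 1][0]
                assert ca_name == cb_name
                assert (ca <= 0) == (cb <= 0)


class TestSerialization:
    def test_round_trip_bit_exact(self, small_index, small_community, tmp_path):
        path = tmp_path / "x.sigf"
        write_index(small_index, path)
        back = read_index(path)
        assert (back.entries == small_index.entries).all()
        assert back.k == small_index.k
        assert back.family == small_index.family
        assert back.genome_table == small_index.genome_table
        assert back.phases_built == small_index.phases_built
        assert back.omega == small_index.omega
        assert back.canonical == small_index.canonical
        # re-querying gives identical calls
        for kmer in list(_genome_kmers(small_community[0], 31, True))[:200]:
            assert classify_kmer(back, kmer) == classify_kmer(small_index, kmer)

    def test_corrupt_magic(self, small_index, tmp_path):
        path = tmp_path / "x.sigf"
        write_index(small_index, path)
        data = bytearray(path.read_bytes())
        data[:4] = b"NOPE"
        path.write_bytes(bytes(data))
        with pytest.raises(IndexFormatError):
            read_index(path)

    def test_truncated_file(self, small_index, tmp_path):
        path = tmp_path / "x.sigf"
        write_index(small_index, path)
        path.write_bytes(path.read_bytes()[:-100])
        with pytest.raises(IndexIntegrityError):
            read_index(path)

    def test_flipped_byte_fails_checksum(self, small_index, tmp_path):
        path = tmp_path / "x.sigf"
        write_index(small_index, path)
        data = bytearray(path.read_bytes())
        data[len(data) // 2] ^= 0xFF
        path.write_bytes(bytes(data))
        with pytest.raises(IndexIntegrityError):
            read_index(path)


@pytest.mark.parametrize(
    "size, width, expected",
    [("8GB", 32, 2 * 2**30), ("8GB", 16, 4 * 2**30), ("1KB", 32, 256), (64, 32, 16)],
)
def test_entries_for_bytes(size, width, expected):
    assert entries_for_bytes(size, width) == expected
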