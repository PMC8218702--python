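"""Two-phase redundancy merge: exact grouping, partial rescue, conservation."""

import random

import pytest

from sorfkit.dedup import merge_catalog, merge_full, merge_partial
from sorfkit.model import ORFRecord, SpliceBlock, SplicingStatus


def rec(chrom="chr1", strand="+", start=100, stop=111, status="unspliced",
        blocks=(), source="s1", **kw):
    return ORFRecord(
        chromosome=chrom, strand=strand, start_pos=start, stop_pos=stop,
        splicing_status=SplicingStatus(status),
        splice_blocks=[SpliceBlock(*b) for b in blocks],
        source_id=source, **kw,
    )


class TestMergeFull:
    def test_identical_entries_from_two_sources_merge(self):
        uniques, leftovers = merge_full([rec(source="s1"), rec(source="s2")])
        assert len(uniques) == 1 and not leftovers
        assert uniques[0].experiment_count == 2
        assert uniques[0].sources == {"s1", "s2"}

    def test_splicing_status_splits_keys(self):
        a = rec(status="unspliced")
        b = rec(start=100, stop=130, status="spliced", blocks=[(100, 109), (120, 130)])
        c = rec(start=100, stop=130, status="unspliced")
        uniques, _ = merge_full([a, b, c])
        assert len(uniques) == 3

    def test_incomplete_keys_become_leftovers(self):
        partial = rec().copy(strand=None)
        uniques, leftovers = merge_full([rec(), partial])
        assert len(uniques) == 1 and leftovers == [partial]

    def test_transcript_union_over_merged_entries(self):
        a = rec(transcript_ids=["T1"])
        b = rec(transcript_ids=["T2"], source="s2")
        (u,), _ = merge_full([a, b])
        assert u.transcript_ids == {"T1", "T2"}


class TestMergePartial:
    def test_strand_and_start_pattern_absorbed(self):
        uniques, _ = merge_full([rec()])
        leftover = rec().copy(stop_pos=None)
        uniques, dropped = merge_partial([leftover], uniques)
        assert dropped == 0
        assert uniques[0].experiment_count == 2

    def test_start_and_stop_pattern_absorbed(self):
        uniques, _ = merge_full([rec()])
        leftover = rec().copy(strand=None)
        _, dropped = merge_partial([leftover], uniques)
        assert dropped == 0

    def test_unmatched_leftover_dropped(self):
        uniques, _ = merge_full([rec()])
        leftover = rec(start=900, stop=911).copy(strand=None)
        _, dropped = merge_partial([leftover], uniques)
        assert dropped == 1

    def test_single_coordinate_never_merges(self):
        uniques, _ = merge_full([rec()])
        leftover = rec().copy(strand=None, stop_pos=None)  # chromosome + start only
        _, dropped = merge_partial([leftover], uniques)
        assert dropped == 1

    def test_length_agreement_breaks_ties(self):
        # two uniques share strand+start; the leftover's reported length
        # matches only the shorter one
        a = rec(stop=111)
        b = rec(stop=141)
        uniques, _ = merge_full([a, b])
        leftover = rec(reported_length_nt=12).copy(stop_pos=None)
        uniques, dropped = merge_partial([leftover], uniques)
        assert dropped == 0
        by_stop = {u.key.stop_pos: u.experiment_count for u in uniques}
        assert by_stop == {111: 2, 141: 1}

    def test_leftover_assigned_to_exactly_one_unique(self):
        uniques, _ = merge_full([rec(stop=111), rec(stop=141)])
        leftover = rec().copy(stop_pos=None)
        uniques, dropped = merge_partial([leftover], uniques)
        assert sum(u.experiment_count for u in uniques) + dropped == 3


# -- oracle: naive exhaustive merge ----------------------------------------

def oracle_merge(records):
    """Independent pairwise-comparison implementation of the merge contract."""
    full = [r for r in records if r.identity_key() is not None]
    leftovers = [r for r in records if r.identity_key() is None]
    groups = {}
    for r in full:
        groups.setdefault(r.identity_key(), []).append(r)
    counts = {k: len(v) for k, v in groups.items()}
    dropped = 0
    for r in leftovers:
        provided = [
            r.strand is not None and r.start_pos is not None,
            r.strand is not None and r.stop_pos is not None,
            r.start_pos is not None and r.stop_pos is not None,
        ]
        if not r.chromosome or not any(provided):
            dropped += 1
            continue
        matches = [
            k for k in counts
            if k.chromosome == r.chromosome
            and (r.strand is None or k.strand == r.strand)
            and (r.start_pos is None or k.start_pos == r.start_pos)
            and (r.stop_pos is None or k.stop_pos == r.stop_pos)
        ]
        if not matches:
            dropped += 1
            continue
        # replicate the deterministic preference cascade by exhaustive ranking
        def rank(k):
            span = abs(k.start_pos - k.stop_pos) + 1
            blocks = k.blocks()
            length = span - sum(b.start - a.end - 1 for a, b in zip(blocks, blocks[1:]))
            len_pref = -(r.reported_length_nt == length) if r.reported_length_nt is not None else 0
            splice_pref = (
                -(k.splicing_status == r.splicing_status.value)
                if r.splicing_status is not SplicingStatus.UNKNOWN else 0
            )
            return (len_pref, 0, splice_pref, -counts[k], k)
        best = min(matches, key=rank)
        counts[best] += 1
    return counts, dropped


def random_catalog(rng, n_records=50, n_keys=20):
    keys = []
    for i in range(n_keys):
        strand = rng.choice("+-")
        lo = 100 + 40 * i
        hi = lo + 3 * rng.randrange(4, 12) - 1
        start, stop = (lo, hi) if strand == "+" else (hi, lo)
        keys.append((strand, start, stop))
    records = []
    for j in range(n_records):
        strand, start, stop = keys[rng.randrange(n_keys)]
        r = rec(strand=strand, start=start, stop=stop, source=f"s{j % 4}")
        roll = rng.random()
        if roll < 0.15:
            r = r.copy(strand=None)
        elif roll < 0.25:
            r = r.copy(stop_pos=None)
        elif roll < 0.3:
            r = r.copy(strand=None, stop_pos=None)  # unusable: single coordinate
        records.append(r)
    return records


class TestMergeProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = random.Random(seed)
        records = random_catalog(rng, n_records=200, n_keys=30)
        uniques, dropped = merge_catalog(records)
        expected_counts, expected_dropped = oracle_merge(records)
        assert {u.key: u.experiment_count for u in uniques} == expected_counts
        assert dropped == expected_dropped

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation(self, seed):
        rng = random.Random(100 + seed)
        records = random_catalog(rng)
        uniques, dropped = merge_catalog(records)
        assert sum(u.experiment_count for u in uniques) + dropped == len(records)

    def test_order_invariance(self):
        rng = random.Random(42)
        records = random_catalog(rng)
        reference = {
            u.key: u.experiment_count for u in merge_catalog(list(records))[0]
        }
        for _ in range(3):
            rng.shuffle(records)
            result = {u.key: u.experiment_count for u in merge_catalog(list(records))[0]}
            assert result == reference

    def test_idempotence_doubles_counts(self):
        rng = random.Random(7)
        records = [r for r in random_catalog(rng) if r.identity_key() is not None]
        uniques, _ = merge_full(records)
        doubled, _ = merge_full(records + list(records))
        assert {u.key for u in doubled} == {u.key for u in uniques}
        counts = {u.key: u.experiment_count for u in uniques}
        for u in doubled:
            assert u.experiment_count == 2 * counts[u.key]

    def test_planted_duplicates_recovered(self, bundle):
        from sorfkit import io as sio
        records = []
        for name, path in bundle.source_paths.items():
            if name.startswith("source") and not name.endswith("_chain"):
                records.extend(sio.read_catalog(path, source_id=name))
        uniques, dropped = merge_catalog(records)
        assert dropped == 0
        got = {str(u.key): u.experiment_count for u in uniques}
        assert got == bundle.manifest.expected_counts
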