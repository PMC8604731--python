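import numpy as np
import pandas as pd
import pytest

from mesomics import SegmentProfile, toy_assembly


@pytest.fixture(scope="session")
def assembly():
    return toy_assembly()


def make_profile(rows, purity=0.8, ploidy=2.0, sample_id="S"):
    """Build a SegmentProfile from (chrom, start, end, total, minor) tuples."""
    seg = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "total_cn", "minor_cn"]
    )
    return SegmentProfile(seg, purity=purity, ploidy=ploidy, sample_id=sample_id)


def diploid_profile(assembly, purity=0.8):
    """Whole-genome heterozygous diploid (total 2, minor 1)."""
    rows = [
        (c, 1, assembly.chromosome_length(c), 2, 1) for c in assembly.chromosomes
    ]
    return make_profile(rows, purity=purity, ploidy=2.0)


def random_profile(rng, assembly, max_segments=8):
    """Random gap-free tiling with a mix of copy states (for oracle tests)."""
    states = [(2, 1), (2, 1), (1, 0), (2, 0), (3, 1), (4, 1), (0, 0), (1, 0), (4, 2)]
    rows = []
    for chrom in assembly.chromosomes:
        length = assembly.chromosome_length(chrom)
        n_seg = int(rng.integers(1, max_segments + 1))
        cuts = np.unique(rng.integers(2, length, size=n_seg - 1)) if n_seg > 1 else []
        bounds = [1, *[int(c) for c in cuts], length + 1]
        for lo, hi in zip(bounds, bounds[1:]):
            if hi <= lo:
                continue
            t, m = states[int(rng.integers(len(states)))]
            rows.append((chrom, lo, hi - 1, t, m))
    ploidy = float(
        sum((r[2] - r[1] + 1) * r[3] for r in rows)
        / sum(r[2] - r[1] + 1 for r in rows)
    )
    return make_profile(rows, purity=float(rng.uniform(0.3, 0.95)),
                        ploidy=max(ploidy, 0.5))


def split_segments(profile, rng, n_extra_cuts=40):
    """Split random segments into state-preserving pieces (metric invariance)."""
    seg = profile.segments.copy()
    for _ in range(n_extra_cuts):
        i = int(rng.integers(len(seg)))
        row = seg.iloc[i]
        if row.end <= row.start:
            continue
        cut = int(rng.integers(row.start, row.end))
        left = row.copy()
        left.end = cut
        right = row.copy()
        right.start = cut + 1
        seg = pd.concat(
            [seg.iloc[:i], pd.DataFrame([left, right]), seg.iloc[i + 1 :]],
            ignore_index=True,
        )
    return SegmentProfile(
        seg, purity=profile.purity, ploidy=profile.ploidy,
        sample_id=profile.sample_id,
    )
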