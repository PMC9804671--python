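"""Bundled illustrative datasets."""

from importlib.resources import files

from .profiles import ProviderSet, QualityScale, read_provider_set

TWO_PRACTICE_SCALE = QualityScale("ordinal", ("poor", "OK", "good"))


def two_practice_example_path():
    """Path to the bundled two-practice example profiles CSV."""
    return files("ordqual").joinpath("data/two_practice_example.csv")


def two_practice_example() -> ProviderSet:
    """The canonical two-practice lottery example.

    Practice A reports 40% poor / 10% OK / 50% good, practice B 30% / 30% /
    40%, with equal registration weights.  A random patient of A beats one of
    B with probability 0.33, loses with 0.32 and ties with 0.35, so the
    pairwise difference — and the two-practice lottery index — is 0.01.
    """
    with two_practice_example_path().open() as fh:
        return read_provider_set(fh, scale=TWO_PRACTICE_SCALE)
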