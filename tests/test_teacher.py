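"""Synthetic-teacher behaviour: pronunciation, noise, approval, dilution."""

import numpy as np
import pytest

from babblelex.perception import SyllableTable
from babblelex.phonology import PhonemeInventory, parse_syllable
from babblelex.production import Utterance
from babblelex.evaluation import salient_rank_advantage
from babblelex.teacher import (
    FUNCTION,
    SALIENT,
    ConfigError,
    TeacherProfile,
    VocabularyEntry,
    default_profile,
    default_vocabulary,
    generate_teacher_utterance,
    ideal_profile,
    load_vocabulary,
    pronounce,
    respond,
)


def _profile(vocab, **kw):
    return TeacherProfile(vocabulary=tuple(vocab), **kw)


RED = VocabularyEntry("red", ("r", "eh", "d"), SALIENT, 1.0)
THAT = VocabularyEntry(
    "that", ("dh", "ae", "t"), FUNCTION, 1.0,
    (("dh", "ae"), ("dh", "ah", "t"), ("dh", "eh", "t")),
)


class TestVocabulary:
    def test_default_file_loads(self):
        vocab = default_vocabulary()
        entries = {e.orth: e for e in vocab}
        assert entries["red"].canonical == ("r", "eh", "d")
        assert entries["red"].role == SALIENT
        assert len(entries["that"].variants) >= 2
        # default profile invariant: function words carry variant pools
        for e in vocab:
            if e.role == FUNCTION:
                assert len(e.variants) >= 2, e.orth

    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "vocab.tsv"
        p.write_text("red\tr eh d\tsalient\t5\nthat\tdh ae t\tfunction\t2\tdh ae|dh ah t\n")
        vocab = load_vocabulary(p)
        assert vocab[0] == VocabularyEntry("red", ("r", "eh", "d"), SALIENT, 5.0)
        assert vocab[1].variants == (("dh", "ae"), ("dh", "ah", "t"))

    def test_bad_role_and_weight_rejected(self):
        with pytest.raises(ConfigError):
            VocabularyEntry("x", ("aa",), "verb", 1.0)
        with pytest.raises(ConfigError):
            VocabularyEntry("x", ("aa",), SALIENT, 0.0)


class TestPronounce:
    def test_salient_always_canonical_at_prob_one(self):
        profile = _profile([RED, THAT])
        rng = np.random.default_rng(0)
        assert all(pronounce(RED, profile, rng) == ("r", "eh", "d") for _ in range(50))

    def test_function_mass_splits_across_variants(self):
        profile = _profile([RED, THAT], canonical_prob_function=0.25)
        rng = np.random.default_rng(1)
        draws = [pronounce(THAT, profile, rng) for _ in range(4000)]
        realisations = {d for d in draws}
        assert realisations == {("dh", "ae", "t")} | set(THAT.variants)
        # no single variant can outrank a stable content word of equal frequency
        top_share = max(draws.count(r) for r in realisations) / len(draws)
        assert top_share < 0.5

    def test_canonical_fraction_binomial(self):
        profile = _profile([RED, THAT], canonical_prob_function=0.5)
        rng = np.random.default_rng(2)
        n = 10_000
        canonical = sum(
            pronounce(THAT, profile, rng) == THAT.canonical for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(canonical / n - 0.5) < 3 * se

    def test_variantless_entry_below_prob_one_is_config_error(self):
        bare = VocabularyEntry("the", ("dh", "ah"), FUNCTION, 1.0)
        profile = _profile([RED, bare], canonical_prob_function=0.9)
        with pytest.raises(ConfigError):
            pronounce(bare, profile, np.random.default_rng(3))


class TestGenerateUtterance:
    def test_degenerate_vocabulary_repeats_word(self):
        profile = _profile([RED], substitution_rate=0.0, deletion_rate=0.0,
                           talkover_drop=0.0)
        words, stream = generate_teacher_utterance(profile, np.random.default_rng(4))
        assert set(words) == {"red"}
        assert stream.tokens == ("r", "eh", "d") * len(words)

    def test_identity_channel_concatenates_canonical_forms(self):
        profile = ideal_profile()
        rng = np.random.default_rng(5)
        forms = {e.orth: e.canonical for e in profile.vocabulary}
        words, stream = generate_teacher_utterance(profile, rng)
        expected = tuple(tok for w in words for tok in forms[w])
        assert stream.tokens == expected

    def test_noise_and_talkover_shrink_or_alter_stream(self):
        profile = _profile([RED], substitution_rate=0.3, deletion_rate=0.3,
                           talkover_drop=0.3, words_per_utterance=30)
        words, stream = generate_teacher_utterance(profile, np.random.default_rng(6))
        assert len(stream.tokens) < 3 * len(words)

    def test_substitution_stays_within_category(self):
        inventory = PhonemeInventory.default()
        profile = _profile([RED], substitution_rate=1.0, deletion_rate=0.0,
                           talkover_drop=0.0, words_per_utterance=4)
        _, stream = generate_teacher_utterance(profile, np.random.default_rng(7))
        for i, tok in enumerate(stream.tokens):
            original = ("r", "eh", "d")[i % 3]
            assert inventory.category(tok) == inventory.category(original)
            assert tok != original


class TestRespond:
    def _utt(self, *texts):
        return Utterance(tuple(parse_syllable(t.split()) for t in texts), 0)

    def test_perfect_hearing_cites_the_word(self):
        profile = _profile([RED, THAT], hearing_prob=1.0, overpraise_prob=0.0)
        event = respond(self._utt("ao s", "r eh d"), profile, np.random.default_rng(8))
        assert event is not None and event.heard_orth == "red"
        assert event.heard_form == ("r", "eh", "d")

    def test_deaf_teacher_never_approves(self):
        profile = _profile([RED, THAT], hearing_prob=0.0, overpraise_prob=0.0)
        rng = np.random.default_rng(9)
        assert all(
            respond(self._utt("r eh d"), profile, rng) is None for _ in range(100)
        )

    def test_overpraise_approves_without_a_word(self):
        profile = _profile([RED, THAT], hearing_prob=1.0, overpraise_prob=1.0)
        event = respond(self._utt("ao s"), profile, np.random.default_rng(10))
        assert event is not None and event.heard_orth is None

    def test_non_canonical_rendering_is_not_noticed(self):
        # the teacher listens for proper word forms, not arbitrary syllables
        profile = _profile([RED, THAT], hearing_prob=1.0, overpraise_prob=0.0)
        event = respond(self._utt("dh ae"), profile, np.random.default_rng(11))
        assert event is None


class TestProfileValidation:
    def test_probabilities_bounded(self):
        with pytest.raises(ConfigError):
            _profile([RED], hearing_prob=1.5)

    def test_default_profile_orders_canonical_probs(self):
        p = default_profile()
        assert p.canonical_prob_content >= p.canonical_prob_function


class TestSessionScaleStatistics:
    def test_salient_forms_dominate_top_perceived_cvc_ranks(self):
        """Over a session-scale corpus (~470 words across seeds), the top 10
        perceived CVC syllables include several salient canonical forms."""
        profile = default_profile()
        salient = set(profile.salient_forms())
        for seed in range(5):
            rng = np.random.default_rng(seed)
            table = SyllableTable()
            words = 0
            turn = 0
            while words < 470:
                ws, stream = generate_teacher_utterance(profile, rng, turn)
                words += len(ws)
                turn += 1
                table.perceive(stream)
            top10 = {p for p, _ in table.rank_syllables("CVC")[:10]}
            assert len(top10 & salient) >= 3, seed


class TestFrequencyDilution:
    def test_lower_function_canonicity_raises_salient_rank_advantage(self):
        """Frequency dilution: spreading function-word mass over variant
        renderings pushes their canonical forms down the perceived CVC
        ranking relative to consistently-pronounced salient words."""

        def mean_advantage(canonical_prob_function, seeds=range(25), n_turns=40):
            advs = []
            for seed in seeds:
                profile = default_profile(
                    canonical_prob_function=canonical_prob_function,
                    substitution_rate=0.0, deletion_rate=0.0, talkover_drop=0.0,
                )
                rng = np.random.default_rng(seed)
                table = SyllableTable()
                for t in range(n_turns):
                    _, stream = generate_teacher_utterance(profile, rng, t)
                    table.perceive(stream)
                advs.append(salient_rank_advantage(table, profile.vocabulary))
            return float(np.mean(advs))

        assert mean_advantage(0.4) > mean_advantage(1.0)
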