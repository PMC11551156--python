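"""Synthetic wheat-variety corpora with overlapping-relation structure.

Real variety-approval text describes one variety per sentence and lists
many attribute values, most carrying units ("827 g/L", "14.8%"), so every
sentence holds several triples sharing a single head entity — the
single-entity-overlap pattern the cascade decoder targets. The generator
emulates that structure with romanized templates::

    Zhongmai 159: unit weight 827 g/L, crude protein content 14.8%.

Each sentence gets a generated variety name as head and k attribute
clauses (relation cue + unit-bearing or categorical tail) drawn without
replacement from the schema; gold character offsets are exact. An optional
distractor clause carries a number bound to no relation, to exercise
false-positive control. A matching random word-vector table is emitted
containing every unit token, cue token and categorical value (unit
L2-normalised vectors), plus random filler words — so candidate-word
matching sees the same boundary cues (e.g. "g/L") the real lexicon would
provide. Everything is reproducible from the seed.

Romanized templates keep fixtures readable while the processing stays
strictly per-character; ``language="zh"`` switches to Chinese templates
("中麦159：容重827克/升，粗蛋白含量14.8%。") with the same gold structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import AnnotatedSentence
from .extractor import Span, Triple
from .lexicon import WordVectorTable, random_table

#: the 23 attribute relations of the wheat-germplasm schema
DEFAULT_RELATIONS = [
    "Growth period", "Winter-spring type", "Plant height", "Maturity",
    "Spike number per mu", "Shell color", "Kernel number", "Seed color",
    "1000-grain weight", "Grain hardness", "Unit weight", "Grain shape",
    "Stability time", "Awn length", "Tensile area", "Leaf color", "Yield",
    "Plant type", "Sowing time", "Crude protein content", "Seeding quantity",
    "Wet gluten content", "Disease susceptibility",
]

VARIETY_PREFIXES = ["Zhongmai", "Jimai", "Zhoumai", "Yannong", "Aikang",
                    "Xinmai", "Bainong", "Shannong", "Luomai", "Zhengmai"]

_COLORS = ["white", "red", "amber", "dark-green", "green", "gray-green"]


def _num(rng, lo, hi, dec=0):
    if dec:
        return f"{rng.uniform(lo, hi):.{dec}f}"
    return str(int(rng.integers(lo, hi + 1)))


#: relation -> (cue phrase, tail generator). Units appear as separate
#: space-delimited tokens except "%", which attaches to its number as in
#: real approval text.
RELATION_TEMPLATES: dict[str, tuple] = {
    "Growth period": ("growth period", lambda rng: f"{_num(rng, 190, 245)} day"),
    "Winter-spring type": ("winter-spring type", lambda rng: str(
        rng.choice(["semi-winter", "winter", "spring", "weak-spring"]))),
    "Plant height": ("plant height", lambda rng: f"{_num(rng, 62, 98)} cm"),
    "Maturity": ("maturity", lambda rng: str(
        rng.choice(["early", "medium-early", "medium", "medium-late"]))),
    "Spike number per mu": ("spike number per mu",
                            lambda rng: f"{_num(rng, 32, 48, 1)} wan"),
    "Shell color": ("shell color", lambda rng: str(rng.choice(_COLORS[:3]))),
    "Kernel number": ("kernel number", lambda rng: f"{_num(rng, 28, 44)} grain"),
    "Seed color": ("seed color", lambda rng: str(rng.choice(_COLORS[:3]))),
    "1000-grain weight": ("1000-grain weight",
                          lambda rng: f"{_num(rng, 36, 54, 1)} g"),
    "Grain hardness": ("grain hardness", lambda rng: _num(rng, 45, 75)),
    "Unit weight": ("unit weight", lambda rng: f"{_num(rng, 770, 840)} g/L"),
    "Grain shape": ("grain shape", lambda rng: str(
        rng.choice(["oval", "round", "elliptical", "oblong"]))),
    "Stability time": ("stability time", lambda rng: f"{_num(rng, 2, 28, 1)} min"),
    "Awn length": ("awn length", lambda rng: str(
        rng.choice(["long-awn", "short-awn", "awnless"]))),
    "Tensile area": ("tensile area", lambda rng: f"{_num(rng, 40, 130)} cm2"),
    "Leaf color": ("leaf color", lambda rng: str(rng.choice(_COLORS[3:]))),
    "Yield": ("yield", lambda rng: f"{_num(rng, 360, 610, 1)} kg/mu"),
    "Plant type": ("plant type", lambda rng: str(
        rng.choice(["compact", "semi-compact", "loose"]))),
    "Sowing time": ("sowing time", lambda rng: str(
        rng.choice(["early-October", "mid-October", "late-October"]))),
    "Crude protein content": ("crude protein content",
                              lambda rng: f"{_num(rng, 12, 17, 1)}%"),
    "Seeding quantity": ("seeding quantity",
                         lambda rng: f"{_num(rng, 8, 14)} kg/mu"),
    "Wet gluten content": ("wet gluten content",
                           lambda rng: f"{_num(rng, 24, 38, 1)}%"),
    "Disease susceptibility": ("disease susceptibility", lambda rng: str(
        rng.choice(["stripe-rust", "powdery-mildew", "leaf-rust",
                    "head-blight"]))),
}

#: unit tokens that may terminate a numeric tail
UNIT_TOKENS = ["g/L", "%", "cm", "day", "g", "wan", "grain", "min", "cm2",
               "kg/mu", "kg"]

ZH_VARIETY_PREFIXES = ["中麦", "济麦", "周麦", "烟农", "矮抗", "新麦",
                       "百农", "山农", "洛麦", "郑麦"]

_ZH_COLORS = ["白色", "红色", "琥珀色", "深绿色", "绿色", "灰绿色"]

ZH_RELATION_TEMPLATES: dict[str, tuple] = {
    "Growth period": ("生育期", lambda rng: f"{_num(rng, 190, 245)}天"),
    "Winter-spring type": ("冬春性", lambda rng: str(
        rng.choice(["半冬性", "冬性", "春性", "弱春性"]))),
    "Plant height": ("株高", lambda rng: f"{_num(rng, 62, 98)}厘米"),
    "Maturity": ("熟期", lambda rng: str(
        rng.choice(["早熟", "中早熟", "中熟", "中晚熟"]))),
    "Spike number per mu": ("亩穗数", lambda rng: f"{_num(rng, 32, 48, 1)}万"),
    "Shell color": ("壳色", lambda rng: str(rng.choice(_ZH_COLORS[:3]))),
    "Kernel number": ("穗粒数", lambda rng: f"{_num(rng, 28, 44)}粒"),
    "Seed color": ("粒色", lambda rng: str(rng.choice(_ZH_COLORS[:3]))),
    "1000-grain weight": ("千粒重", lambda rng: f"{_num(rng, 36, 54, 1)}克"),
    "Grain hardness": ("籽粒硬度", lambda rng: _num(rng, 45, 75)),
    "Unit weight": ("容重", lambda rng: f"{_num(rng, 770, 840)}克/升"),
    "Grain shape": ("籽粒形状", lambda rng: str(
        rng.choice(["椭圆形", "圆形", "长圆形", "卵圆形"]))),
    "Stability time": ("稳定时间", lambda rng: f"{_num(rng, 2, 28, 1)}分钟"),
    "Awn length": ("芒长", lambda rng: str(rng.choice(["长芒", "短芒", "无芒"]))),
    "Tensile area": ("拉伸面积", lambda rng: f"{_num(rng, 40, 130)}平方厘米"),
    "Leaf color": ("叶色", lambda rng: str(rng.choice(_ZH_COLORS[3:]))),
    "Yield": ("产量", lambda rng: f"{_num(rng, 360, 610, 1)}公斤/亩"),
    "Plant type": ("株型", lambda rng: str(
        rng.choice(["紧凑", "半紧凑", "松散"]))),
    "Sowing time": ("播期", lambda rng: str(
        rng.choice(["十月上旬", "十月中旬", "十月下旬"]))),
    "Crude protein content": ("粗蛋白含量", lambda rng: f"{_num(rng, 12, 17, 1)}%"),
    "Seeding quantity": ("播量", lambda rng: f"{_num(rng, 8, 14)}公斤/亩"),
    "Wet gluten content": ("湿面筋含量", lambda rng: f"{_num(rng, 24, 38, 1)}%"),
    "Disease susceptibility": ("感病性", lambda rng: str(
        rng.choice(["条锈病", "白粉病", "叶锈病", "赤霉病"]))),
}

ZH_UNIT_TOKENS = ["克/升", "%", "厘米", "天", "克", "万", "粒", "分钟",
                  "平方厘米", "公斤/亩", "公斤"]

_ROMAN_CATEGORICALS = (_COLORS + [
    "semi-winter", "winter", "spring", "weak-spring", "early", "medium-early",
    "medium", "medium-late", "oval", "round", "elliptical", "oblong",
    "long-awn", "short-awn", "awnless", "compact", "semi-compact", "loose",
    "early-October", "mid-October", "late-October", "stripe-rust",
    "powdery-mildew", "leaf-rust", "head-blight"])

_ZH_CATEGORICALS = (_ZH_COLORS + [
    "半冬性", "冬性", "春性", "弱春性", "早熟", "中早熟", "中熟", "中晚熟",
    "椭圆形", "圆形", "长圆形", "卵圆形", "长芒", "短芒", "无芒", "紧凑",
    "半紧凑", "松散", "十月上旬", "十月中旬", "十月下旬", "条锈病",
    "白粉病", "叶锈病", "赤霉病"])

#: per-language template packs: relation templates, unit tokens, variety
#: prefixes, categorical lexicon entries, and punctuation/layout
LANGUAGES: dict[str, dict] = {
    "roman": {
        "templates": RELATION_TEMPLATES,
        "units": UNIT_TOKENS,
        "prefixes": VARIETY_PREFIXES,
        "categoricals": _ROMAN_CATEGORICALS,
        "name_sep": " ",
        "colon": ":",
        "clause_sep": ", ",
        "first_sep": " ",
        "period": ".",
        "distractor": "report code ",
    },
    "zh": {
        "templates": ZH_RELATION_TEMPLATES,
        "units": ZH_UNIT_TOKENS,
        "prefixes": ZH_VARIETY_PREFIXES,
        "categoricals": _ZH_CATEGORICALS,
        "name_sep": "",
        "colon": "：",
        "clause_sep": "，",
        "first_sep": "",
        "period": "。",
        "distractor": "备案号",
    },
}


@dataclass
class SynthConfig:
    n_sentences: int = 100
    schema: list[str] = field(default_factory=lambda: list(DEFAULT_RELATIONS))
    tails_per_head: tuple[int, int] = (2, 6)
    units: list[str] | None = None      #: default: the language's unit tokens
    distractor_rate: float = 0.3
    lexicon_size: int = 300
    word_dim: int = 200
    language: str = "roman"
    seed: int = 0
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be >= 1")
        if not self.schema:
            raise ValueError("relation schema must be non-empty")
        lo, hi = self.tails_per_head
        if lo < 1 or hi < lo:
            raise ValueError("invalid tails_per_head range")
        if not (0.0 <= self.distractor_rate <= 1.0):
            raise ValueError("distractor_rate must lie in [0, 1]")
        if self.language not in LANGUAGES:
            raise ValueError(f"language must be one of {sorted(LANGUAGES)}")
        if self.units is None:
            self.units = list(LANGUAGES[self.language]["units"])
        unknown = [r for r in self.schema
                   if r not in LANGUAGES[self.language]["templates"]]
        if unknown:
            raise ValueError(f"no template for relations: {unknown}")


@dataclass
class SynthCorpus:
    train: list[AnnotatedSentence]
    dev: list[AnnotatedSentence]
    test: list[AnnotatedSentence]
    table: WordVectorTable
    schema: list[str]

    @property
    def all_sentences(self) -> list[AnnotatedSentence]:
        return self.train + self.dev + self.test


def _variety_name(rng: np.random.Generator, lang: dict,
                  used: set[str]) -> str:
    while True:
        name = (f"{rng.choice(lang['prefixes'])}{lang['name_sep']}"
                f"{int(rng.integers(1, 1000))}")
        if name not in used:
            used.add(name)
            return name


def make_sentence(rng: np.random.Generator, config: SynthConfig,
                  used_names: set[str]) -> AnnotatedSentence:
    """One variety sentence; guaranteed >= 2 triples sharing the head span
    whenever the configured tail range allows it."""
    lang = LANGUAGES[config.language]
    templates = lang["templates"]
    k_lo, k_hi = config.tails_per_head
    k = int(rng.integers(k_lo, min(k_hi, len(config.schema)) + 1))
    rels = [config.schema[i]
            for i in rng.choice(len(config.schema), size=k, replace=False)]
    name = _variety_name(rng, lang, used_names)
    head = Span(0, len(name), name)
    text = name + lang["colon"]
    triples: list[Triple] = []
    clauses: list[tuple[str | None, str]] = []
    for rel in rels:
        cue, tail_maker = templates[rel]
        gap = "" if config.language == "zh" else " "
        clauses.append((rel, f"{cue}{gap}__TAIL__{tail_maker(rng)}"))
    if rng.random() < config.distractor_rate:
        distractor = f"{lang['distractor']}__TAIL__{int(rng.integers(1000, 9999))}"
        clauses.insert(int(rng.integers(0, len(clauses) + 1)), (None, distractor))
    for i, (rel, clause) in enumerate(clauses):
        sep = lang["first_sep"] if i == 0 else lang["clause_sep"]
        prefix, tail_text = clause.split("__TAIL__")
        text += sep + prefix
        start = len(text)
        text += tail_text
        if rel is not None:
            triples.append(Triple(head=head, relation=rel,
                                  tail=Span(start, len(text), tail_text)))
    text += lang["period"]
    return AnnotatedSentence(text=text, triples=triples)


def _lexicon_words(config: SynthConfig, rng: np.random.Generator) -> list[str]:
    lang = LANGUAGES[config.language]
    words: list[str] = []
    seen: set[str] = set()

    def add(w: str) -> None:
        if w and " " not in w and w not in seen:
            seen.add(w)
            words.append(w)

    for u in config.units:
        add(u)
    for rel in config.schema:
        cue, _ = lang["templates"][rel]
        for token in cue.split():
            add(token)
    for cat in lang["categoricals"]:
        add(cat)
    for prefix in lang["prefixes"]:
        add(prefix)
    alphabet = list("abcdefghijklmnopqrstuvwxyz")
    while len(words) < config.lexicon_size:
        length = int(rng.integers(3, 8))
        add("".join(rng.choice(alphabet, size=length)))
    return words


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate disjoint train/dev/test splits plus the word-vector table."""
    rng = np.random.default_rng(config.seed)
    words = _lexicon_words(config, rng)
    table = random_table(words, config.word_dim, rng)
    used_names: set[str] = set()
    sentences = [make_sentence(rng, config, used_names)
                 for _ in range(config.n_sentences)]
    for s in sentences:
        s.validate(config.schema)
    f_train, f_dev, _ = config.splits
    n = len(sentences)
    n_train = int(round(f_train * n))
    n_dev = int(round(f_dev * n))
    return SynthCorpus(
        train=sentences[:n_train],
        dev=sentences[n_train:n_train + n_dev],
        test=sentences[n_train + n_dev:],
        table=table,
        schema=list(config.schema),
    )
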