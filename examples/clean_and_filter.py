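"""Clean raw posts and apply the study inclusion filter.

Cleaning strips URLs, mentions, retweet markers, hashtag sigils, emoji and
stray symbols; the inclusion filter then keeps English posts containing the
keyword "insomnia" as a whole word.
"""

from datetime import datetime, timezone

from sentifuse import Corpus, TweetRecord, clean_text, filter_inclusion, word_count

raw_posts = [
    "Can't sleep \U0001f62b #insomnia again... https://t.co/xyz @friend",
    "RT @bot: buy pillows now http://spam.example",
    "I'm an insomniac, always have been",
    "Third night of insomnia this week",
]

ts = datetime(2020, 3, 1, 2, 30, tzinfo=timezone.utc)
corpus = Corpus(
    [TweetRecord(f"t{i}", text, ts, lang="en") for i, text in enumerate(raw_posts)]
)

for record in corpus:
    record.clean_text = clean_text(record.text)
    print(f"raw:   {record.text}")
    print(f"clean: {record.clean_text!r}  ({word_count(record.text)} words)")
    print()

result = filter_inclusion(corpus, keyword="insomnia", lang="en")
print(f"kept {len(result.corpus)} of {len(corpus)}: "
      f"{[r.id for r in result.corpus]}")
print(f"excluded by reason: {dict(result.excluded)}")
print()
print("t0 passes (hashtag sigil stripped, 'insomnia' remains a word);")
print("t1 lacks the keyword; t2 fails word-boundary matching ('insomniac').")
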