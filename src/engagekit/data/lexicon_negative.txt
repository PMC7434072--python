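# Bundled general-purpose negative word list (one token per line).
# Small by design; swap in a larger dictionary via load_lexicon().
afraid
angry
annoyed
annoying
anxiety
anxious
ashamed
awful
bad
bitter
bleak
broken
cruel
cry
crying
damage
dangerous
defeat
defeated
depressed
depressing
depression
desperate
difficult
disappointed
disappointing
disappointment
discouraged
disgusting
distress
doubt
dread
dreadful
fail
failed
failure
fear
fearful
frustrated
frustrating
frustration
gloomy
grief
guilt
guilty
hard
harm
harmful
hate
hated
helpless
hopeless
horrible
hurt
hurting
irritable
irritated
jealous
lonely
lose
losing
loss
lost
mad
miserable
misery
moody
nasty
negative
nervous
pain
painful
panic
pathetic
pessimistic
poor
regret
relapse
resent
sad
sadness
scared
shaky
shame
sick
sorrow
sorry
stress
stressed
stressful
struggle
struggling
stupid
suffer
suffering
terrible
terrified
tired
tough
tragic
trouble
ugly
unbearable
uncomfortable
unfair
unhappy
unlucky
upset
useless
weak
weary
worried
worry
worse
worst
worthless
wretched
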