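# Bundled general-purpose positive word list (one token per line).
# Small by design; swap in a larger dictionary via load_lexicon().
amazing
admirable
awesome
beautiful
benefit
beneficial
best
better
blessed
brave
bright
brilliant
calm
capable
celebrate
celebration
cheer
cheerful
comfort
comfortable
commend
confident
congrats
congratulations
courage
courageous
delight
delighted
determined
eager
easier
easy
encourage
encouraged
encouraging
enjoy
enjoyed
excellent
excited
exciting
fabulous
fantastic
favorite
fortunate
friendly
fun
generous
gentle
glad
good
grateful
great
happiness
happy
healthy
helpful
hero
hope
hopeful
hug
hugs
impressive
improve
improved
improvement
inspire
inspired
inspiring
joy
joyful
kind
kindness
laugh
laughter
love
loved
lovely
loving
lucky
marvelous
motivated
motivating
nice
optimistic
outstanding
peaceful
perfect
pleasant
pleased
positive
proud
reassuring
relief
relieved
remarkable
rewarding
safe
satisfied
smile
splendid
strength
strong
stronger
succeed
success
successful
superb
support
supportive
terrific
thankful
thanks
thrilled
triumph
trust
uplifting
victory
warm
welcome
win
winner
wonderful
worthy
yay
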