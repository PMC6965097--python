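ABOUT
ABOVE
ABUSE
ACTOR
ACUTE
ADMIT
ADOPT
ADULT
AFTER
AGAIN
AGENT
AGONY
AGREE
AHEAD
ALARM
ALBUM
ALERT
ALIKE
ALIVE
ALLOW
ALONE
ALONG
ALTER
AMONG
AMUSE
ANGEL
ANGER
ANGLE
ANGRY
ANKLE
ANNEX
ANNOY
ANNUL
APART
APPLE
APPLY
ARENA
ARGUE
ARISE
ARMOR
AROSE
ARRAY
ARROW
ASIDE
ASSET
ATONE
AUDIO
AUDIT
AUNTS
AVOID
AWAKE
AWARD
AWARE
BADGE
BADLY
BAKER
BANAL
BANDS
BANJO
BASIC
BASIN
BATCH
BEACH
BEARD
BEAST
BEGAN
BEGIN
BEGUN
BEING
BELLY
BELOW
BENCH
BERRY
BINGE
BIRTH
BLACK
BLADE
BLAME
BLAND
BLANK
BLAST
BLAZE
BLEED
BLEND
BLESS
BLIND
BLOCK
BLOND
BLOOD
BLOOM
BLOWN
BLUES
BLUFF
BLUNT
BLURB
BLUSH
BOARD
BONUS
BOOST
BOOTH
BOUND
BRAIN
BRAKE
BRAND
BRASS
BRAVE
BREAD
BREAK
BREED
BRICK
BRIDE
BRIEF
BRINE
BRING
BRINK
BRINY
BROAD
BROKE
BROWN
BRUNT
BRUSH
BRUTE
BUDDY
BUILD
BUILT
BUNCH
BUNNY
BURNT
BURST
BUYER
CABIN
CABLE
CACHE
CAMEL
CANAL
CANDY
CANNY
CANOE
CARGO
CARRY
CARVE
CATCH
CAUSE
CEASE
CENTS
CHAIN
CHAIR
CHALK
CHAOS
CHARM
CHART
CHASE
CHEAP
CHEAT
CHECK
CHEEK
CHEER
CHESS
CHEST
CHIEF
CHILD
CHILL
CHOIR
CHOSE
CHUNK
CHUTE
CINCH
CIVIC
CIVIL
CLAIM
CLASH
CLASS
CLEAN
CLEAR
CLERK
CLICK
CLIFF
CLIMB
CLOCK
CLOSE
CLOTH
CLOUD
CLUMP
CLUNG
COACH
COAST
COCOA
COLON
COLOR
COMIC
CONCH
CONDO
CORAL
CORNY
COUCH
COUGH
COULD
COUNT
COURT
COVER
CRACK
CRAFT
CRANE
CRANK
CRASH
CRAZY
CREAM
CREEK
CREST
CRIME
CRISP
CRONE
CRONY
CROSS
CROWD
CROWN
CRUDE
CRUEL
CRUMB
CRUSH
CRUST
CURVE
CYCLE
CYNIC
DAILY
DAIRY
DANCE
DANDY
DATED
DEALT
DEATH
DEBUT
DECAY
DECOR
DELAY
DELTA
DEMON
DENIM
DENSE
DEPTH
DERBY
DEVIL
DIARY
DIGIT
DINER
DINGY
DIRTY
DITCH
DIVER
DIZZY
DODGE
DONOR
DONUT
DOUBT
DOUGH
DOUSE
DOZEN
DRAFT
DRAIN
DRAMA
DRANK
DREAM
DRESS
DRIED
DRIFT
DRILL
DRINK
DRIVE
DRONE
DROVE
DROWN
DRUID
DRUNK
DUNCE
DUNES
DYING
EAGER
EAGLE
EARLY
EARTH
EIGHT
ELBOW
ELDER
ELECT
ELITE
EMPTY
ENEMY
ENJOY
ENNUI
ENTER
ENTRY
EQUAL
EQUIP
ERROR
ESSAY
EVENT
EVERY
EXACT
EXAMS
EXIST
EXTRA
EXULT
FAINT
FAIRY
FAITH
FALSE
FANCY
FATAL
FAULT
FAUNA
FAVOR
FEAST
FENCE
FERRY
FEVER
FIBER
FIELD
FIEND
FIFTH
FIFTY
FIGHT
FINAL
FINCH
FINER
FIRST
FLAME
FLASH
FLEET
FLESH
FLINT
FLOAT
FLOCK
FLOOD
FLOOR
FLOUR
FLUID
FLUKE
FLUNG
FLUSH
FLUTE
FOCUS
FORCE
FORGE
FORTH
FORTY
FORUM
FOUND
FRAME
FRANK
FRAUD
FRESH
FRONT
FROST
FROZE
FRUIT
FUNDS
FUNGI
FUNKY
FUNNY
GAUGE
GAUNT
GAUZE
GENIE
GENRE
GHOST
GIANT
GIVEN
GLAND
GLASS
GLOBE
GLORY
GLOVE
GOING
GONER
GRACE
GRADE
GRAIN
GRAND
GRANT
GRAPE
GRAPH
GRASP
GRASS
GRAVE
GREAT
GREED
GREEN
GREET
GRIEF
GRILL
GRIND
GROAN
GROSS
GROUP
GROVE
GROWN
GRUEL
GRUFF
GRUNT
GUARD
GUESS
GUEST
GUIDE
GUILT
HABIT
HANDY
HAPPY
HARSH
HASTE
HATCH
HAUNT
HAVEN
HEART
HEAVY
HEDGE
HELLO
HENCE
HERBS
HINGE
HONEY
HONOR
HORSE
HOTEL
HOUND
HOUSE
HUMAN
HUMID
HUMOR
HUNCH
HURRY
HYENA
IDEAL
IMAGE
IMPLY
INDEX
INNER
INPUT
IRONY
ISSUE
IVORY
JAUNT
JEANS
JELLY
JEWEL
JOINT
JOLLY
JUDGE
JUICE
JUICY
JUNTA
KNEEL
KNELT
KNIFE
KNOCK
KNOWN
KNURL
LABEL
LABOR
LANCE
LARGE
LASER
LATER
LAUGH
LAYER
LEARN
LEASE
LEAST
LEAVE
LEGAL
LEMON
LEVEL
LIGHT
LIMIT
LINEN
LINER
LINGO
LIVER
LOBBY
LOCAL
LODGE
LOGIC
LONER
LOOSE
LORRY
LOUSE
LOVER
LOWER
LOYAL
LUCKY
LUNAR
LUNCH
LUNGE
LYING
MAGIC
MAJOR
MAKER
MANGO
MANIA
MANIC
MANOR
MAPLE
MARCH
MARRY
MATCH
MAUVE
MAYBE
MAYOR
MEANT
MEDAL
MEDIA
MELON
MERCY
MERGE
MERIT
MERRY
METAL
METER
MIDST
MIGHT
MINCE
MINER
MINOR
MINTY
MINUS
MIXED
MODEL
MOIST
MONEY
MONTH
MORAL
MOTOR
MOUND
MOUNT
MOUSE
MOUTH
MOVIE
MUNCH
MUSIC
NAIVE
NAKED
NANNY
NASTY
NAVAL
NERVE
NEVER
NEWLY
NIGHT
NINTH
NOBLE
NOISE
NORTH
NOTED
NOUNS
NOVEL
NURSE
NYLON
OCCUR
OCEAN
OFFER
OFTEN
OLIVE
ONION
ONSET
OPERA
ORBIT
ORDER
ORGAN
OTHER
OUGHT
OUNCE
OUTER
OWNED
OWNER
OXIDE
PAINT
PANDA
PANEL
PANIC
PAPER
PARTY
PASTA
PATCH
PAUSE
PEACE
PEACH
PEARL
PEDAL
PENAL
PENNY
PHASE
PHONE
PHOTO
PIANO
PIECE
PILOT
PINCH
PITCH
PIVOT
PIZZA
PLACE
PLAIN
PLANE
PLANK
PLANT
PLATE
PLAZA
PLEAD
PLUCK
PLUMB
PLUME
PLUMP
POINT
POLAR
PORCH
POUCH
POUND
POWER
PRANK
PRESS
PRICE
PRIDE
PRIME
PRINT
PRIOR
PRIZE
PROBE
PRONE
PRONG
PROOF
PROUD
PROVE
PROXY
PRUNE
PULSE
PUNCH
PUPIL
PUREE
PURSE
QUEEN
QUERY
QUEST
QUEUE
QUICK
QUIET
QUILT
QUITE
QUOTA
QUOTE
RADAR
RADIO
RAISE
RALLY
RANCH
RANDY
RANGE
RAPID
RATIO
REACH
REACT
READY
REALM
REBEL
REFER
REIGN
RELAX
RENAL
REPLY
RHINO
RIDER
RIDGE
RIFLE
RIGHT
RIGID
RISEN
RIVAL
RIVER
ROAST
ROBIN
ROBOT
ROCKY
ROGUE
ROMAN
ROUGE
ROUGH
ROUND
ROUSE
ROUTE
ROYAL
RUGBY
RULER
RUMOR
RUNNY
RUNTS
RURAL
SADLY
SAINT
SALAD
SALON
SANDY
SANER
SAUCE
SAUNA
SCALE
SCARE
SCARF
SCENE
SCENT
SCOPE
SCORE
SCOUT
SCRAP
SCREW
SCUBA
SEIZE
SENSE
SERVE
SEVEN
SHADE
SHAFT
SHAKE
SHALL
SHAME
SHAPE
SHARE
SHARP
SHEEP
SHEET
SHELF
SHELL
SHIFT
SHINE
SHINY
SHIRT
SHOCK
SHONE
SHOOK
SHOOT
SHORE
SHORT
SHOUT
SHOWN
SHRUG
SHUNT
SIEGE
SIGHT
SILLY
SINCE
SIXTH
SIXTY
SKILL
SKULK
SKULL
SKUNK
SLAVE
SLEEP
SLEPT
SLICE
SLIDE
SLOPE
SLUMP
SLUNG
SMALL
SMART
SMELL
SMILE
SMOKE
SNACK
SNAKE
SOLAR
SOLID
SOLVE
SONAR
SONIC
SORRY
SOUND
SOUTH
SPACE
SPARE
SPARK
SPEAK
SPEED
SPELL
SPEND
SPENT
SPICE
SPICY
SPINE
SPITE
SPLIT
SPOKE
SPOON
SPORT
SPRAY
SPURN
SPURT
STAFF
STAGE
STAIR
STAKE
STAMP
STAND
STARE
START
STATE
STEAK
STEAL
STEAM
STEEL
STEEP
STEER
STERN
STICK
STIFF
STILL
STING
STOCK
STOLE
STONE
STOOD
STOOL
STORE
STORM
STORY
STOVE
STRAP
STRAW
STRIP
STUCK
STUDY
STUFF
STUMP
STUNG
STUNT
STYLE
SUGAR
SUITE
SUNNY
SUPER
SURGE
SWAMP
SWEAR
SWEAT
SWEEP
SWEET
SWEPT
SWIFT
SWING
SWORD
SWORE
SYNOD
TABLE
TAKEN
TANGO
TANGY
TASTE
TAUNT
TAXES
TEACH
TEETH
TEMPO
TENET
TENOR
TENSE
TENTH
THANK
THEFT
THEIR
THEME
THERE
THESE
THICK
THIEF
THIGH
THING
THINK
THIRD
THOSE
THREE
THREW
THROW
THUMB
TIGER
TIGHT
TIMER
TIRED
TITLE
TODAY
TOKEN
TONAL
TONER
TONIC
TOOTH
TOPIC
TORCH
TOTAL
TOUCH
TOUGH
TOWEL
TOWER
TOXIC
TRACE
TRACK
TRADE
TRAIL
TRAIN
TRAIT
TRANS
TRASH
TREAT
TREND
TRIAL
TRIBE
TRICK
TRIED
TRUCE
TRUCK
TRULY
TRUNK
TRUST
TRUTH
TULIP
TUNER
TUNIC
TUTOR
TWICE
TWIST
ULCER
ULTRA
UNCLE
UNDER
UNDUE
UNFIT
UNION
UNITE
UNITY
UNTIL
UPPER
UPSET
URBAN
USAGE
USHER
USUAL
UTTER
VAGUE
VALID
VALUE
VALVE
VAPOR
VAULT
VENOM
VENUE
VERSE
VIDEO
VILLA
VINYL
VIRUS
VISIT
VITAL
VIVID
VOCAL
VOICE
VOTER
VOUCH
VOWEL
WAGON
WAIST
WANDS
WASTE
WATCH
WATER
WEAVE
WEDGE
WEIGH
WEIRD
WHALE
WHEAT
WHEEL
WHERE
WHICH
WHILE
WHITE
WHOLE
WHOSE
WIDEN
WIDOW
WIDTH
WINCE
WINCH
WINDY
WOMAN
WOMEN
WORLD
WORRY
WORSE
WORST
WORTH
WOULD
WOUND
WRIST
WRITE
WRONG
WROTE
YACHT
YIELD
YOUNG
YOUTH
ZONAL
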